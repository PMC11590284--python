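"""Ground-truth plasmid bins from hybrid assemblies and alignment hits.

Hybrid (short + long read) assemblies yield closed, often circular contigs
that serve as full plasmid references.  Hybrid contigs are classified by
circularity and length: circular and longer than 500,000 bp → chromosome,
circular and shorter → plasmid, everything else → ambiguous.  Short-read
contigs are then mapped onto the hybrid contigs (BLAST-style tabular hits);
hits with identity below 95% or covering less than 80% of the short-read
contig are discarded, and each plasmid-labelled hybrid contig defines one
ground-truth bin holding every query contig with a surviving hit to it.
A query hitting two plasmids lands in both bins, creating a repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .bins_io import BinSet, ConsistencyError, read_tsv

logger = logging.getLogger(__name__)

CHROMOSOME_LENGTH_BP = 500_000
DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MIN_COVERAGE = 80.0

#: standard 12-column tabular alignment output (BLAST outfmt 6)
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class HybridContig:
    id: str
    length: int
    circular: bool

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"hybrid contig {self.id!r}: length must be >= 1 bp")


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment of a short-read contig (query) to a hybrid contig."""

    query: str
    subject: str
    identity: float
    aln_length: int
    query_length: int
    qstart: int | None = None
    qend: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity must lie in [0, 100], got {self.identity}")
        if self.aln_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.query_length < 1:
            raise ValueError("query length must be >= 1")

    @property
    def coverage(self) -> float:
        """Per-hit query coverage in percent."""
        return 100.0 * self.aln_length / self.query_length


def classify_hybrid_contig(contig: HybridContig) -> str:
    """'chromosome' | 'plasmid' | 'ambiguous' from circularity and length.

    The 500,000 bp rule speaks of strictly longer/shorter; a circular contig
    of exactly 500,000 bp is neither, and is labelled plasmid (logged as a
    boundary case) — plasmids of that size exist, half-megabase chromosomes
    do not.
    """
    if contig.circular:
        if contig.length > CHROMOSOME_LENGTH_BP:
            return "chromosome"
        if contig.length == CHROMOSOME_LENGTH_BP:
            logger.warning(
                "hybrid contig %s is exactly %d bp; labelled plasmid",
                contig.id, CHROMOSOME_LENGTH_BP,
            )
        return "plasmid"
    return "ambiguous"


def read_hybrid_metadata(path: str | Path) -> list[HybridContig]:
    """Read hybrid-contig metadata from TSV columns id, length, circular."""
    table = read_tsv(path, dtype=str)
    for col in ("id", "length", "circular"):
        if col not in table.columns:
            raise ConsistencyError(f"{path}: missing required column {col!r}")
    out = []
    for row in table.itertuples(index=False):
        circ = str(row.circular).strip().lower()
        if circ not in {"true", "false"}:
            raise ConsistencyError(f"{path}: circular must be true/false, got {row.circular!r}")
        out.append(HybridContig(str(row.id), int(row.length), circ == "true"))
    return out


def read_blast_hits(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[AlignmentHit]:
    """Read 12-column tabular alignments, attaching query lengths.

    The tabular dialect carries identity and alignment length but not the
    query length, which must be supplied separately (e.g. from the assembly
    FASTA via :func:`plascompare.bins_io.lengths_from_fasta`).
    """
    table = read_tsv(path, header=None, names=BLAST6_COLUMNS)
    hits = []
    for row in table.itertuples(index=False):
        query = str(row.qseqid)
        if query not in query_lengths:
            raise ConsistencyError(f"{path}: no length known for query {query!r}")
        hits.append(
            AlignmentHit(
                query=query,
                subject=str(row.sseqid),
                identity=float(row.pident),
                aln_length=int(row.length),
                query_length=int(query_lengths[query]),
                qstart=int(row.qstart),
                qend=int(row.qend),
            )
        )
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    merge_intervals: bool = False,
) -> list[AlignmentHit]:
    """Keep hits with identity ≥ min_identity and query coverage ≥ min_coverage.

    The discarding thresholds are strict ("below 95%", "less than 80%"), so
    boundary hits survive.  Coverage is per hit by default.  With
    ``merge_intervals`` the query intervals of all identity-passing hits of
    one (query, subject) pair are unioned first and the pair's hits are kept
    when the merged coverage reaches the threshold — for mappers that
    fragment one homologous region into several hits.
    """
    passing_identity = [h for h in hits if h.identity >= min_identity]
    if not merge_intervals:
        return [h for h in passing_identity if h.coverage >= min_coverage]

    by_pair: dict[tuple[str, str], list[AlignmentHit]] = {}
    for hit in passing_identity:
        by_pair.setdefault((hit.query, hit.subject), []).append(hit)
    kept: list[AlignmentHit] = []
    for pair_hits in by_pair.values():
        if any(h.qstart is None or h.qend is None for h in pair_hits):
            raise ValueError("merge_intervals requires qstart/qend on every hit")
        intervals = sorted(
            (min(h.qstart, h.qend), max(h.qstart, h.qend)) for h in pair_hits
        )
        covered = 0
        cur_lo, cur_hi = intervals[0]
        for lo, hi in intervals[1:]:
            if lo <= cur_hi + 1:
                cur_hi = max(cur_hi, hi)
            else:
                covered += cur_hi - cur_lo + 1
                cur_lo, cur_hi = lo, hi
        covered += cur_hi - cur_lo + 1
        if 100.0 * covered / pair_hits[0].query_length >= min_coverage:
            kept.extend(pair_hits)
    kept.sort(key=lambda h: (h.query, h.subject, h.qstart or 0))
    return kept


def build_truth_bins(
    hits: Sequence[AlignmentHit],
    hybrid_contigs: Sequence[HybridContig],
    label: str = "ground_truth",
) -> BinSet:
    """One bin per plasmid-labelled hybrid contig, from filtered hits.

    A bin holds every query contig with at least one surviving hit to the
    plasmid (several hits collapse to one membership); queries hitting
    several plasmids appear in several bins, creating repeat families.
    Plasmids with no surviving hit yield no bin.
    """
    plasmids = {c.id for c in hybrid_contigs if classify_hybrid_contig(c) == "plasmid"}
    bins: dict[str, set[str]] = {}
    lengths: dict[str, int] = {}
    for hit in hits:
        if hit.subject not in plasmids:
            continue
        if hit.query in lengths and lengths[hit.query] != hit.query_length:
            raise ConsistencyError(
                f"query {hit.query!r} reported with two lengths "
                f"({lengths[hit.query]} and {hit.query_length})"
            )
        lengths[hit.query] = hit.query_length
        bins.setdefault(hit.subject, set()).add(hit.query)
    return BinSet(
        label=label,
        bins={bid: frozenset(cs) for bid, cs in bins.items()},
        lengths=lengths,
    )
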