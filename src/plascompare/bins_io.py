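"""Reading, validating, filtering and writing plasmid-bin assignments.

A *plasmid bin* is an unordered set of contigs predicted (or known) to
originate from one plasmid.  Bin assignments are exchanged as headered,
UTF-8, tab-separated tables with columns ``plasmid``, ``contig`` and
``contig_len``; lines starting with ``#`` are comments.  A contig id may
occur in several bins of one assignment (a cross-bin repeat, typically an
insertion sequence) but never twice within one bin — binning tools treat a
bin as a set, not a multiset, and so do we.

Contig lengths may alternatively be taken from the assembly FASTA; when both
sources are given they must agree exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import fsum
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: reserved for renamed copies of repeated contigs (see :mod:`plascompare.repeats`)
RESERVED_CHAR = "#"

REQUIRED_COLUMNS = ("plasmid", "contig", "contig_len")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV skipping whole lines that start with '#'.

    pandas' ``comment`` option truncates anywhere in a line, which would eat
    legitimate '#' characters inside fields; only line-initial comments are
    part of the dialect.
    """
    import io

    text = Path(path).read_text(encoding="utf-8")
    kept = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    return pd.read_csv(io.StringIO(kept), sep="\t", **kwargs)


class BinFormatError(ValueError):
    """The input table does not conform to the bin-TSV dialect."""


class ConsistencyError(ValueError):
    """Contradictory information (e.g. two lengths for one contig id)."""


def _check_token(token: str, what: str, allow_reserved: bool = False) -> None:
    if not token:
        raise BinFormatError(f"empty {what} id")
    if any(ws in token for ws in ("\t", "\n", "\r")):
        raise BinFormatError(f"{what} id {token!r} contains whitespace control characters")
    if not allow_reserved and RESERVED_CHAR in token:
        raise BinFormatError(
            f"{what} id {token!r} contains the reserved character {RESERVED_CHAR!r}"
        )


def _check_length(cid: str, length: object) -> int:
    try:
        as_int = int(length)
    except (TypeError, ValueError):
        raise BinFormatError(f"contig {cid!r}: length {length!r} is not an integer") from None
    if isinstance(length, float) and length != as_int:
        raise BinFormatError(f"contig {cid!r}: length {length!r} is not an integer")
    if as_int < 1:
        raise BinFormatError(f"contig {cid!r}: length must be >= 1 bp, got {as_int}")
    return as_int


@dataclass(frozen=True)
class Contig:
    """A contig: an identifier with a length in base pairs."""

    id: str
    length: int

    def __post_init__(self) -> None:
        _check_token(self.id, "contig", allow_reserved=True)
        _check_length(self.id, self.length)


@dataclass
class BinSet:
    """A named collection of plasmid bins over a contig universe.

    Parameters
    ----------
    label:
        Free-text origin of the assignment (a tool name or ``"ground_truth"``).
    bins:
        Mapping from bin id to the (frozen) set of contig ids in that bin.
        Every bin is non-empty; a contig may appear in several bins.
    lengths:
        Mapping from contig id to its length in bp; must cover every contig
        occurring in any bin.
    """

    label: str
    bins: dict[str, frozenset[str]]
    lengths: dict[str, int]
    _allow_reserved: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.bins = {bid: frozenset(cs) for bid, cs in self.bins.items()}
        self.lengths = {c: int(l) for c, l in self.lengths.items()}
        for bid, contigs in self.bins.items():
            _check_token(bid, "bin", allow_reserved=True)
            if not contigs:
                raise BinFormatError(f"bin {bid!r} is empty")
            for cid in contigs:
                _check_token(cid, "contig", allow_reserved=self._allow_reserved)
                if cid not in self.lengths:
                    raise ConsistencyError(f"contig {cid!r} in bin {bid!r} has no length entry")
        for cid, length in self.lengths.items():
            _check_length(cid, length)

    # -- basic queries ----------------------------------------------------

    @property
    def contig_ids(self) -> set[str]:
        """All contig ids occurring in at least one bin."""
        out: set[str] = set()
        for contigs in self.bins.values():
            out |= contigs
        return out

    def copy_number(self, cid: str) -> int:
        """Number of bins containing *cid* (0 if absent)."""
        return sum(1 for contigs in self.bins.values() if cid in contigs)

    def bins_containing(self, cid: str) -> list[str]:
        """Sorted ids of the bins containing *cid*."""
        return sorted(bid for bid, contigs in self.bins.items() if cid in contigs)

    def is_repeat_free(self) -> bool:
        """True when no contig occurs in more than one bin."""
        seen: set[str] = set()
        for contigs in self.bins.values():
            if seen & contigs:
                return False
            seen |= contigs
        return True

    def occurrence_weight(self, alpha: float) -> float:
        """Sum of ℓ(c)^α over every contig *occurrence* (copy number counts)."""
        return fsum(
            self.lengths[c] ** alpha for contigs in self.bins.values() for c in contigs
        )

    def bin_contents(self) -> tuple[frozenset[str], ...]:
        """The bins as a canonically ordered tuple of contig-id sets.

        Bin ids are labels only; two assignments are the same partition-like
        object when their bin contents coincide as multisets.
        """
        return tuple(sorted(self.bins.values(), key=lambda s: sorted(s)))

    def same_bins(self, other: "BinSet") -> bool:
        """Whether the two assignments have identical bin contents."""
        return self.bin_contents() == other.bin_contents()


# -- readers / writers ----------------------------------------------------


def read_bins(path: str | Path, label: str, dedupe: bool = False) -> BinSet:
    """Read a bin assignment from a headered TSV (plasmid, contig, contig_len).

    Rows repeating the same (plasmid, contig) pair are an error — a bin is a
    set, not a multiset — unless ``dedupe`` is set, in which case they collapse
    to one occurrence with a logged warning.
    """
    path = Path(path)
    try:
        table = read_tsv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise BinFormatError(f"{path}: no data rows") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise BinFormatError(f"{path}: missing required column(s) {missing}")

    bins: dict[str, set[str]] = {}
    lengths: dict[str, int] = {}
    for row in table.itertuples(index=False):
        bid = str(getattr(row, "plasmid"))
        cid = str(getattr(row, "contig"))
        _check_token(bid, "bin", allow_reserved=True)
        _check_token(cid, "contig")
        length = _check_length(cid, getattr(row, "contig_len"))
        if cid in lengths and lengths[cid] != length:
            raise ConsistencyError(
                f"{path}: contig {cid!r} has two lengths ({lengths[cid]} and {length})"
            )
        lengths[cid] = length
        members = bins.setdefault(bid, set())
        if cid in members:
            if not dedupe:
                raise BinFormatError(
                    f"{path}: contig {cid!r} occurs twice in bin {bid!r}; "
                    "within-bin repeats are not modelled (pass dedupe to collapse)"
                )
            logger.warning("%s: collapsed duplicate row (%s, %s)", path, bid, cid)
        members.add(cid)
    return BinSet(label=label, bins={b: frozenset(c) for b, c in bins.items()}, lengths=lengths)


def write_bins(bs: BinSet, path: str | Path) -> None:
    """Write a BinSet in the TSV dialect read by :func:`read_bins`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("plasmid\tcontig\tcontig_len\n")
        for bid in sorted(bs.bins):
            for cid in sorted(bs.bins[bid]):
                fh.write(f"{bid}\t{cid}\t{bs.lengths[cid]}\n")


def lengths_from_fasta(path: str | Path) -> dict[str, int]:
    """Contig lengths (sequence character counts) from a FASTA file."""
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise ConsistencyError(f"{path}: duplicate FASTA record id {record.id!r}")
        if len(record.seq) == 0:
            raise BinFormatError(f"{path}: record {record.id!r} has an empty sequence")
        lengths[record.id] = len(record.seq)
    return lengths


# -- transforms -----------------------------------------------------------


def filter_min_length(bs: BinSet, min_len: int) -> BinSet:
    """Drop every contig shorter than ``min_len`` bp from every bin.

    Bins emptied by the filter are dropped (a bin must be non-empty for its
    split/join cost to be defined).  ``min_len=0`` is the identity; the
    operation is idempotent.  The input is not modified.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    new_bins: dict[str, frozenset[str]] = {}
    for bid, contigs in bs.bins.items():
        kept = frozenset(c for c in contigs if bs.lengths[c] >= min_len)
        if kept:
            new_bins[bid] = kept
    used = set().union(*new_bins.values()) if new_bins else set()
    return BinSet(
        label=bs.label,
        bins=new_bins,
        lengths={c: bs.lengths[c] for c in used},
        _allow_reserved=bs._allow_reserved,
    )


def validate_pair(a: BinSet, b: BinSet) -> dict[str, int]:
    """Check length agreement across two assignments; return the union mapping."""
    conflicts = sorted(
        cid
        for cid in set(a.lengths) & set(b.lengths)
        if a.lengths[cid] != b.lengths[cid]
    )
    if conflicts:
        raise ConsistencyError(
            "conflicting contig lengths between the two bin sets: " + ", ".join(conflicts)
        )
    merged = dict(a.lengths)
    merged.update(b.lengths)
    return merged
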