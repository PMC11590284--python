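"""Seeded synthetic bin sets with a known edit structure.

Real benchmark pairs (tool output vs ground truth) differ by exactly four
kinds of discrepancy: extra contigs, missing contigs, true bins split across
predicted bins and true bins joined into one predicted bin — plus repeats
created by contigs shared between plasmids.  This module generates bin sets
and applies a controlled, logged number of each edit kind so that every
metric module can be exercised, at any scale, without external data.  All
randomness flows from a single integer seed and the log suffices to replay
the derivation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable

from .bins_io import BinSet

EDIT_KINDS = ("drop_contig", "add_contig", "duplicate_into_bin", "split", "join")


class PerturbationError(ValueError):
    """The requested edit counts cannot be applied to the given bin set."""


@dataclass(frozen=True)
class Edit:
    kind: str
    details: tuple

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass(frozen=True)
class PerturbationLog:
    seed: int
    edits: tuple[Edit, ...]


def generate_binset(
    seed: int,
    n_bins: int = 5,
    contigs_per_bin: tuple[int, int] = (2, 6),
    length_range: tuple[int, int] = (500, 100_000),
    label: str | None = None,
    prefix: str = "c",
    bin_prefix: str = "B",
) -> BinSet:
    """A reproducible repeat-free bin set with uniform random lengths.

    Defaults sketch a plasmid-scale instance: a handful of bins of 2–6
    contigs with lengths between 0.5 and 100 kbp (the size range spanned by
    typical plasmid-derived short-read contigs).  Fixed seed, fixed output.
    """
    lo, hi = contigs_per_bin
    if n_bins < 0 or lo < 1 or hi < lo:
        raise ValueError("invalid bin/contig count ranges")
    llo, lhi = length_range
    if llo < 1 or lhi < llo:
        raise ValueError("invalid length range")
    rng = random.Random(seed)
    bins: dict[str, frozenset[str]] = {}
    lengths: dict[str, int] = {}
    counter = 0
    for b in range(1, n_bins + 1):
        size = rng.randint(lo, hi)
        members = []
        for _ in range(size):
            counter += 1
            cid = f"{prefix}{counter}"
            lengths[cid] = rng.randint(llo, lhi)
            members.append(cid)
        bins[f"{bin_prefix}{b}"] = frozenset(members)
    return BinSet(label=label or f"synthetic_seed{seed}", bins=bins, lengths=lengths)


def _fresh(base: str, existing: Iterable[str]) -> str:
    taken = set(existing)
    i = 1
    while f"{base}{i}" in taken:
        i += 1
    return f"{base}{i}"


def perturb(
    bs: BinSet,
    seed: int,
    n_splits: int = 0,
    n_joins: int = 0,
    n_extra: int = 0,
    n_missing: int = 0,
    n_duplicate: int = 0,
) -> tuple[BinSet, PerturbationLog]:
    """Apply exactly the requested edit counts; return the result and a log.

    Edits apply in kind order — drops, additions, duplications, splits,
    joins — with seeded choices within each kind.  The input is never
    modified; an infeasible request (e.g. a split when every bin is a
    singleton) raises before anything is returned.  Replaying the log on the
    source reproduces the result (:func:`replay`).
    """
    for count in (n_splits, n_joins, n_extra, n_missing, n_duplicate):
        if count < 0:
            raise ValueError("edit counts must be non-negative")
    rng = random.Random(seed)
    bins = {bid: set(cs) for bid, cs in bs.bins.items()}
    lengths = dict(bs.lengths)
    edits: list[Edit] = []

    for _ in range(n_missing):
        universe = sorted({c for cs in bins.values() for c in cs})
        if not universe:
            raise PerturbationError("cannot drop a contig from an empty bin set")
        cid = rng.choice(universe)
        edits.append(Edit("drop_contig", (cid,)))
        _apply_drop(bins, cid)

    for _ in range(n_extra):
        cid = _fresh("x", lengths)
        length = rng.randint(min(lengths.values(), default=500), max(lengths.values(), default=100_000))
        target = rng.choice(sorted(bins)) if bins else _fresh("Bx", bins)
        edits.append(Edit("add_contig", (cid, length, target)))
        _apply_add(bins, lengths, cid, length, target)

    for _ in range(n_duplicate):
        candidates = [
            (cid, bid)
            for bid in sorted(bins)
            for cid in sorted({c for cs in bins.values() for c in cs})
            if cid not in bins[bid]
        ]
        if not candidates:
            raise PerturbationError("no (contig, bin) pair available for duplication")
        cid, bid = rng.choice(candidates)
        edits.append(Edit("duplicate_into_bin", (cid, bid)))
        bins[bid].add(cid)

    for _ in range(n_splits):
        splittable = sorted(bid for bid, cs in bins.items() if len(cs) >= 2)
        if not splittable:
            raise PerturbationError("no bin with >= 2 contigs left to split")
        bid = rng.choice(splittable)
        members = sorted(bins[bid])
        size = rng.randint(1, len(members) - 1)
        moved = tuple(sorted(rng.sample(members, size)))
        new_bid = _fresh(f"{bid}.s", bins)
        edits.append(Edit("split", (bid, new_bid, moved)))
        _apply_split(bins, bid, new_bid, moved)

    for _ in range(n_joins):
        if len(bins) < 2:
            raise PerturbationError("need at least two bins to join")
        keep, absorb = rng.sample(sorted(bins), 2)
        edits.append(Edit("join", (keep, absorb)))
        _apply_join(bins, keep, absorb)

    used = set().union(*bins.values()) if bins else set()
    out = BinSet(
        label=f"{bs.label}+perturbed",
        bins={bid: frozenset(cs) for bid, cs in bins.items()},
        lengths={c: lengths[c] for c in used},
    )
    return out, PerturbationLog(seed=seed, edits=tuple(edits))


def replay(bs: BinSet, log: PerturbationLog) -> BinSet:
    """Re-apply a perturbation log to its source bin set."""
    bins = {bid: set(cs) for bid, cs in bs.bins.items()}
    lengths = dict(bs.lengths)
    for edit in log.edits:
        if edit.kind == "drop_contig":
            _apply_drop(bins, edit.details[0])
        elif edit.kind == "add_contig":
            _apply_add(bins, lengths, *edit.details)
        elif edit.kind == "duplicate_into_bin":
            cid, bid = edit.details
            bins[bid].add(cid)
        elif edit.kind == "split":
            _apply_split(bins, *edit.details)
        elif edit.kind == "join":
            _apply_join(bins, *edit.details)
    used = set().union(*bins.values()) if bins else set()
    return BinSet(
        label=f"{bs.label}+perturbed",
        bins={bid: frozenset(cs) for bid, cs in bins.items()},
        lengths={c: lengths[c] for c in used},
    )


def _apply_drop(bins: dict[str, set[str]], cid: str) -> None:
    for bid in list(bins):
        bins[bid].discard(cid)
        if not bins[bid]:
            del bins[bid]


def _apply_add(
    bins: dict[str, set[str]], lengths: dict[str, int], cid: str, length: int, bid: str
) -> None:
    lengths[cid] = length
    bins.setdefault(bid, set()).add(cid)


def _apply_split(
    bins: dict[str, set[str]], bid: str, new_bid: str, moved: tuple[str, ...]
) -> None:
    bins[bid] -= set(moved)
    bins[new_bid] = set(moved)
    if not bins[bid]:
        del bins[bid]


def _apply_join(bins: dict[str, set[str]], keep: str, absorb: str) -> None:
    bins[keep] |= bins.pop(absorb)
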