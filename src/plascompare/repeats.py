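"""Repeat-aware dissimilarity via maximal matchings and branch-and-bound.

A contig occurring in k1 bins of the left set and k2 bins of the right set
forms a *repeat family* whenever k1 + k2 > 2 (insertion sequences and other
mobile repeats routinely produce such families).  Each family is resolved by
a maximal matching: min(k1, k2) edges pair one copy on each side, matched
copies are renamed to a shared fresh id, and unmatched copies get fresh
side-local ids and hence count as one-sided contigs.  The dissimilarity of
the pair is the minimum, over all combinations of per-family matchings, of
the repeat-free dissimilarity of the resolved instance.

The minimum is found exactly by a branch-and-bound over a search tree whose
level i fixes the matching of the i-th family.  The bound relies on
monotonicity: adding the copies of a further family can never decrease the
dissimilarity of the partial instance, so a node whose partial value already
reaches the incumbent cannot lead to an improvement.  An exhaustive
Cartesian-product evaluator is provided as an independent oracle for
testing; it is never used by the search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb, factorial
from typing import Iterator, Mapping, Sequence

from .bins_io import BinSet, validate_pair
from .dissimilarity import (
    ComparisonResult,
    FamilyMatching,
    build_result,
    check_alpha,
    component_totals,
    dissimilarity_no_repeats,
    occurrence_denominator,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepeatFamily:
    """All copies of one contig id across both bin sets (k1 + k2 > 2).

    ``bins_left`` / ``bins_right`` list the containing bin ids in sorted
    order, so k1 = len(bins_left) and k2 = len(bins_right).
    """

    contig_id: str
    bins_left: tuple[str, ...]
    bins_right: tuple[str, ...]

    @property
    def k1(self) -> int:
        return len(self.bins_left)

    @property
    def k2(self) -> int:
        return len(self.bins_right)


@dataclass
class SearchStats:
    """Search-tree accounting for the branch-and-bound (debug/regression)."""

    nodes: int = 0
    pruned: int = 0
    leaves: int = 0
    incumbent_updates: int = 0


def repeat_families(a: BinSet, b: BinSet) -> tuple[RepeatFamily, ...]:
    """All contig families needing resolution, sorted by contig id.

    A family qualifies when its copies must be renamed for the repeat-free
    computation to apply, i.e. max(k1, k2) >= 2.  This covers every
    k1 + k2 > 2 family and additionally the one-sided doubles (2, 0)/(0, 2),
    whose sum is 2 but which still repeat within one side; their resolution
    is unique (the empty matching), so including them changes no score.
    """
    validate_pair(a, b)
    ids = a.contig_ids | b.contig_ids
    fams = []
    for cid in sorted(ids):
        left = tuple(a.bins_containing(cid))
        right = tuple(b.bins_containing(cid))
        if max(len(left), len(right)) >= 2:
            fams.append(RepeatFamily(cid, left, right))
    return tuple(fams)


def count_matchings(k1: int, k2: int) -> int:
    """C(max(k1,k2), min(k1,k2)) · min(k1,k2)! maximal matchings."""
    if k1 < 0 or k2 < 0:
        raise ValueError("copy counts must be non-negative")
    lo, hi = sorted((k1, k2))
    return comb(hi, lo) * factorial(lo)


def enumerate_matchings(family: RepeatFamily) -> Iterator[FamilyMatching]:
    """All maximal matchings of one family, in a fixed deterministic order.

    The copies of the smaller side, in sorted bin order, are paired with
    every ordered selection of bins from the larger side; the first matching
    yielded is the identity-order pairing (i-th with i-th).
    """
    left, right = family.bins_left, family.bins_right
    if len(left) <= len(right):
        for chosen in itertools.permutations(right, len(left)):
            rest = tuple(b for b in right if b not in chosen)
            yield FamilyMatching(
                family.contig_id, tuple(zip(left, chosen)), (), rest
            )
    else:
        for chosen in itertools.permutations(left, len(right)):
            rest = tuple(b for b in left if b not in chosen)
            yield FamilyMatching(
                family.contig_id, tuple(zip(chosen, right)), rest, ()
            )


def _renamed_ids(family: RepeatFamily, matching: FamilyMatching):
    """(left additions, right additions) as lists of (bin id, fresh contig id).

    Edge i gets the shared id ``cid#i``; unmatched copies continue the
    numbering, so all k1 + k2 copies receive distinct labels except matched
    pairs, which deliberately share one.  ``#`` is rejected in user contig
    ids, so fresh ids cannot collide.
    """
    cid = family.contig_id
    left_add: list[tuple[str, str]] = []
    right_add: list[tuple[str, str]] = []
    idx = 0
    for left_bin, right_bin in matching.edges:
        idx += 1
        fresh = f"{cid}#{idx}"
        left_add.append((left_bin, fresh))
        right_add.append((right_bin, fresh))
    for left_bin in matching.unmatched_left:
        idx += 1
        left_add.append((left_bin, f"{cid}#{idx}"))
    for right_bin in matching.unmatched_right:
        idx += 1
        right_add.append((right_bin, f"{cid}#{idx}"))
    return left_add, right_add


def resolve(
    a: BinSet,
    b: BinSet,
    matchings: Mapping[str, FamilyMatching] | Sequence[FamilyMatching],
) -> tuple[BinSet, BinSet]:
    """Apply one matching per repeat family, returning repeat-free bin sets.

    Matched copies are renamed to a shared fresh id; unmatched copies become
    one-sided contigs under fresh side-local ids.  Lengths are inherited from
    the family's contig, so total per-occurrence weighted length is conserved.
    """
    if not isinstance(matchings, Mapping):
        matchings = {m.contig_id: m for m in matchings}
    fams = repeat_families(a, b)
    missing = [f.contig_id for f in fams if f.contig_id not in matchings]
    if missing:
        raise ValueError(f"no matching supplied for repeat families: {missing}")

    new_a = {bid: set(cs) for bid, cs in a.bins.items()}
    new_b = {bid: set(cs) for bid, cs in b.bins.items()}
    lengths = dict(a.lengths)
    lengths.update(b.lengths)
    for fam in fams:
        matching = matchings[fam.contig_id]
        _check_matching(fam, matching)
        left_add, right_add = _renamed_ids(fam, matching)
        for bid in fam.bins_left:
            new_a[bid].discard(fam.contig_id)
        for bid in fam.bins_right:
            new_b[bid].discard(fam.contig_id)
        for bid, fresh in left_add:
            new_a[bid].add(fresh)
            lengths[fresh] = lengths[fam.contig_id]
        for bid, fresh in right_add:
            new_b[bid].add(fresh)
            lengths[fresh] = lengths[fam.contig_id]

    def mk(label, bins_dict):
        bins = {bid: frozenset(cs) for bid, cs in bins_dict.items() if cs}
        used = set().union(*bins.values()) if bins else set()
        return BinSet(
            label=label,
            bins=bins,
            lengths={c: lengths[c] for c in used},
            _allow_reserved=True,
        )

    return mk(a.label, new_a), mk(b.label, new_b)


def _check_matching(fam: RepeatFamily, matching: FamilyMatching) -> None:
    left_used = [e[0] for e in matching.edges] + list(matching.unmatched_left)
    right_used = [e[1] for e in matching.edges] + list(matching.unmatched_right)
    if sorted(left_used) != sorted(fam.bins_left) or sorted(right_used) != sorted(
        fam.bins_right
    ):
        raise ValueError(
            f"matching for {fam.contig_id!r} does not cover its copies exactly "
            f"(left {fam.bins_left}, right {fam.bins_right})"
        )
    if len(matching.edges) != min(fam.k1, fam.k2):
        raise ValueError(
            f"matching for {fam.contig_id!r} is not maximal: expected "
            f"{min(fam.k1, fam.k2)} edges, got {len(matching.edges)}"
        )


# -- exact optimisation ----------------------------------------------------


def dissimilarity(
    a: BinSet,
    b: BinSet,
    alpha: float,
    *,
    stats: SearchStats | None = None,
    prune: bool = True,
    check_bound: bool = False,
) -> ComparisonResult:
    """Exact repeat-aware dissimilarity: minimum over all repeat resolutions.

    Falls back to the closed-form repeat-free computation when the pair has
    no repeat family.  ``prune=False`` disables bounding (full enumeration
    through the same tree; used to verify that pruning is lossless) and
    ``check_bound=True`` asserts monotonicity of the partial value along
    every explored edge.  ``stats`` collects node/prune counts.
    """
    alpha = check_alpha(alpha)
    validate_pair(a, b)
    fams = repeat_families(a, b)
    if not fams:
        return dissimilarity_no_repeats(a, b, alpha)

    # branch on the widest families first so the bound prunes large subtrees
    fam_lengths = {f.contig_id: (a.lengths.get(f.contig_id) or b.lengths[f.contig_id]) for f in fams}
    order = sorted(
        fams,
        key=lambda f: (-count_matchings(f.k1, f.k2), -fam_lengths[f.contig_id], f.contig_id),
    )
    per_family = [list(enumerate_matchings(f)) for f in order]

    lengths = dict(a.lengths)
    lengths.update(b.lengths)
    for fam in fams:
        for i in range(1, fam.k1 + fam.k2 + 1):
            lengths[f"{fam.contig_id}#{i}"] = lengths[fam.contig_id]

    repeat_ids = {f.contig_id for f in fams}
    bins_a = {bid: {c for c in cs if c not in repeat_ids} for bid, cs in a.bins.items()}
    bins_b = {bid: {c for c in cs if c not in repeat_ids} for bid, cs in b.bins.items()}

    def total_of() -> float:
        extra, missing, splits, joins = component_totals(bins_a, bins_b, lengths, alpha)
        return extra + missing + splits + joins

    def apply(level: int, matching: FamilyMatching):
        left_add, right_add = _renamed_ids(order[level], matching)
        for bid, fresh in left_add:
            bins_a[bid].add(fresh)
        for bid, fresh in right_add:
            bins_b[bid].add(fresh)
        return left_add, right_add

    def undo(added) -> None:
        left_add, right_add = added
        for bid, fresh in left_add:
            bins_a[bid].discard(fresh)
        for bid, fresh in right_add:
            bins_b[bid].discard(fresh)

    if stats is None:
        stats = SearchStats()

    # incumbent: the identity-order resolution (first matching of each family)
    incumbent_matchings = [ms[0] for ms in per_family]
    added_all = [apply(i, m) for i, m in enumerate(incumbent_matchings)]
    best_extra, best_missing, best_splits, best_joins = component_totals(
        bins_a, bins_b, lengths, alpha
    )
    best_total = best_extra + best_missing + best_splits + best_joins
    best_matchings = tuple(incumbent_matchings)
    for added in reversed(added_all):
        undo(added)

    n_levels = len(order)

    def search(level: int, parent_total: float) -> None:
        nonlocal best_total, best_extra, best_missing, best_splits, best_joins
        nonlocal best_matchings
        for matching in per_family[level]:
            stats.nodes += 1
            added = apply(level, matching)
            extra, missing, splits, joins = component_totals(
                bins_a, bins_b, lengths, alpha
            )
            total = extra + missing + splits + joins
            if check_bound and total < parent_total - 1e-9:
                raise AssertionError(
                    "monotone bound violated: partial dissimilarity decreased "
                    f"({parent_total} -> {total}) at family {matching.contig_id!r}"
                )
            if prune and total >= best_total:
                stats.pruned += 1
                undo(added)
                continue
            if level == n_levels - 1:
                stats.leaves += 1
                if total < best_total:
                    best_total = total
                    best_extra, best_missing = extra, missing
                    best_splits, best_joins = splits, joins
                    chosen = _current_path[: level] + [matching]
                    best_matchings = tuple(chosen)
                    stats.incumbent_updates += 1
            else:
                _current_path[level] = matching
                search(level + 1, total)
            undo(added)

    _current_path: list[FamilyMatching | None] = [None] * n_levels
    search(0, 0.0)
    logger.debug(
        "repeat search: %d families, %d nodes, %d pruned, %d leaves, %d improvements",
        n_levels,
        stats.nodes,
        stats.pruned,
        stats.leaves,
        stats.incumbent_updates,
    )

    matchings_out = tuple(sorted(best_matchings, key=lambda m: m.contig_id))
    return build_result(
        alpha,
        best_extra,
        best_missing,
        best_splits,
        best_joins,
        occurrence_denominator(a, b, alpha),
        matchings_out,
    )


def exhaustive_dissimilarity(
    a: BinSet, b: BinSet, alpha: float, cap: int = 100_000
) -> ComparisonResult:
    """Minimum dissimilarity by evaluating every combination of matchings.

    A brute-force oracle: the Cartesian product over the per-family matching
    sets is materialised and each resolution scored independently of the
    branch-and-bound.  Refuses instances whose product of matching counts
    exceeds ``cap``.
    """
    alpha = check_alpha(alpha)
    fams = repeat_families(a, b)
    if not fams:
        return dissimilarity_no_repeats(a, b, alpha)
    n_combos = 1
    for fam in fams:
        n_combos *= count_matchings(fam.k1, fam.k2)
    if n_combos > cap:
        raise ValueError(
            f"{n_combos} matching combinations exceed the exhaustive cap of {cap}"
        )
    denominator = occurrence_denominator(a, b, alpha)
    best: ComparisonResult | None = None
    for combo in itertools.product(*(list(enumerate_matchings(f)) for f in fams)):
        ra, rb = resolve(a, b, combo)
        res = dissimilarity_no_repeats(ra, rb, alpha)
        if best is None or res.total < best.total:
            best = build_result(
                alpha,
                res.cost_extra,
                res.cost_missing,
                res.cost_splits,
                res.cost_joins,
                denominator,
                tuple(sorted(combo, key=lambda m: m.contig_id)),
            )
    assert best is not None
    return best
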