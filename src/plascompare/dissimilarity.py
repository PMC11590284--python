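"""Split/join dissimilarity between two repeat-free sets of plasmid bins.

The dissimilarity D_α(A, B) measures the cost of transforming one set of
plasmid bins into another by a most parsimonious sequence of bin *splits*
followed by bin *joins*, after discarding the contigs present on only one
side.  For a set of contigs X, its weighted length is
L_α(X) = (Σ_{c∈X} ℓ(c))^α with α ∈ [0, 1]; splitting a bin into two parts
costs the smaller of the two parts' weighted lengths, and joining is the
symmetric operation with the same cost.  α interpolates between pure edit
counting (α = 0, every operation and every one-sided contig costs 1) and
pure length weighting (α = 1).

The total decomposes exactly into four components:

* ``extra``   — contigs present only in the left set, Σ ℓ(c)^α;
* ``missing`` — contigs present only in the right set;
* ``splits``  — cost of refining each left bin into its intersections with
  the right bins (closed form: Σ L_α(part) − max L_α(part) per bin);
* ``joins``   — the symmetric cost of assembling each right bin from the
  refinement.

The normalized score d_α divides the total by the summed per-occurrence
weights of both sides and lies in [0, 1]: it is 0 exactly when the two
assignments have identical bin contents and 1 exactly when they share no
contig.  Assignments with repeated contigs are handled by
:mod:`plascompare.repeats`, which reduces them to this repeat-free core.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import fsum
from typing import Mapping, Sequence

from .bins_io import BinSet

ABS_TOL = 1e-9


class RepeatFamilyError(ValueError):
    """A repeated contig was found where a repeat-free instance is required."""


def check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha


@dataclass(frozen=True)
class FamilyMatching:
    """One resolution of a repeated contig: pairings of its copies.

    ``edges`` pairs a left-side bin with a right-side bin (one copy each);
    there are exactly min(k1, k2) edges.  Copies left unmatched are listed
    per side.  Defined here to keep :class:`ComparisonResult` self-contained;
    constructed by :mod:`plascompare.repeats`.
    """

    contig_id: str
    edges: tuple[tuple[str, str], ...]
    unmatched_left: tuple[str, ...] = ()
    unmatched_right: tuple[str, ...] = ()


@dataclass(frozen=True)
class ComparisonResult:
    """The dissimilarity between two bin sets and its exact breakdown.

    Raw components sum to ``total`` and normalized components to
    ``normalized_total`` (within floating tolerance); ``normalized_total``
    lies in [0, 1].  ``matchings`` records the optimal repeat resolution
    (empty when the inputs were repeat-free).
    """

    alpha: float
    cost_extra: float
    cost_missing: float
    cost_splits: float
    cost_joins: float
    total: float
    denominator: float
    normalized_extra: float
    normalized_missing: float
    normalized_splits: float
    normalized_joins: float
    normalized_total: float
    matchings: tuple[FamilyMatching, ...] = ()

    def components(self) -> dict[str, float]:
        return {
            "splits": self.cost_splits,
            "joins": self.cost_joins,
            "extra": self.cost_extra,
            "missing": self.cost_missing,
        }

    def normalized_components(self) -> dict[str, float]:
        return {
            "splits": self.normalized_splits,
            "joins": self.normalized_joins,
            "extra": self.normalized_extra,
            "missing": self.normalized_missing,
        }


# -- elementary costs -----------------------------------------------------


def weighted_length(contig_ids, lengths: Mapping[str, int], alpha: float) -> float:
    """L_α(X) = (Σ ℓ(c))^α for a non-empty set of contig ids."""
    if not contig_ids:
        raise ValueError("weighted_length of an empty contig set is undefined")
    return float(sum(lengths[c] for c in contig_ids)) ** check_alpha(alpha)


def split_cost_single(
    part1, part2, lengths: Mapping[str, int], alpha: float
) -> float:
    """Cost of one split of a bin into two disjoint non-empty parts.

    min(L_α(P'), L_α(P'')); by symmetry also the cost of the join merging
    the same two parts.
    """
    p1, p2 = frozenset(part1), frozenset(part2)
    if not p1 or not p2:
        raise ValueError("both parts of a split must be non-empty")
    if p1 & p2:
        raise ValueError("split parts must be disjoint")
    return min(weighted_length(p1, lengths, alpha), weighted_length(p2, lengths, alpha))


def refinement_cost(
    parts: Sequence[frozenset[str]], lengths: Mapping[str, int], alpha: float
) -> float:
    """Minimum cost of producing the given parts from their union by splits.

    Closed form: Σ_i L_α(P_i) − max_i L_α(P_i).  A most parsimonious split
    sequence detaches the parts in increasing order of weight, paying each
    part except the heaviest; by split/join symmetry the same value is the
    minimum cost of joining the parts back into the union.
    """
    check_alpha(alpha)
    if not parts:
        return 0.0
    weights = [weighted_length(p, lengths, alpha) for p in parts]
    return float(sum(weights) - max(weights))


# -- set-level operations -------------------------------------------------


def _owner_map(bs: BinSet) -> dict[str, str]:
    """contig id -> containing bin id; raises on repeats."""
    owners: dict[str, str] = {}
    for bid, contigs in bs.bins.items():
        for cid in contigs:
            if cid in owners:
                raise RepeatFamilyError(
                    f"contig {cid!r} occurs in bins {owners[cid]!r} and {bid!r} of "
                    f"{bs.label!r}; resolve repeats via plascompare.repeats.dissimilarity"
                )
            owners[cid] = bid
    return owners


def unique_contigs(a: BinSet, b: BinSet) -> tuple[set[str], set[str]]:
    """Contigs occurring on only one side: (only in *a*, only in *b*)."""
    ua, ub = set(_owner_map(a)), set(_owner_map(b))
    return ua - ub, ub - ua


def refine(
    bin_contigs, other: BinSet, lengths: Mapping[str, int] | None = None
) -> tuple[frozenset[str], ...]:
    """The unique partition of a bin induced by the bins of the other set.

    Each part is the non-empty intersection of the bin with exactly one bin
    of ``other``; every contig of the bin must occur in ``other`` (call after
    one-sided contigs have been removed).  Parts are returned in a
    deterministic order (by smallest contig id).
    """
    owners = _owner_map(other)
    groups: dict[str, set[str]] = {}
    for cid in bin_contigs:
        if cid not in owners:
            raise ValueError(
                f"contig {cid!r} is absent from {other.label!r}; "
                "refinement is defined only after removing one-sided contigs"
            )
        groups.setdefault(owners[cid], set()).add(cid)
    return tuple(sorted((frozenset(g) for g in groups.values()), key=lambda s: min(s)))


# -- the dissimilarity on plain dicts (shared with the repeat search) ------


def component_totals(
    bins_a: Mapping[str, frozenset[str] | set[str]],
    bins_b: Mapping[str, frozenset[str] | set[str]],
    lengths: Mapping[str, int],
    alpha: float,
) -> tuple[float, float, float, float]:
    """(extra, missing, splits, joins) for repeat-free bin dicts.

    Assumes repeat-freeness on each side; empty bins are ignored.  This is
    the inner loop of the repeat branch-and-bound, hence the plain-dict
    interface.
    """
    owner_a: dict[str, str] = {}
    for bid, contigs in bins_a.items():
        for cid in contigs:
            owner_a[cid] = bid
    owner_b: dict[str, str] = {}
    for bid, contigs in bins_b.items():
        for cid in contigs:
            owner_b[cid] = bid

    # fsum: correctly rounded independent of iteration order, so e.g. the
    # one-sided mass of a disjoint pair equals the denominator bit-for-bit
    extra = fsum(lengths[c] ** alpha for c in owner_a if c not in owner_b)
    missing = fsum(lengths[c] ** alpha for c in owner_b if c not in owner_a)

    def one_side(bins, owner_other):
        costs = []
        for contigs in bins.values():
            sums: dict[str, int] = {}
            for cid in contigs:
                other_bin = owner_other.get(cid)
                if other_bin is not None:
                    sums[other_bin] = sums.get(other_bin, 0) + lengths[cid]
            if len(sums) > 1:
                weights = sorted(s**alpha for s in sums.values())
                costs.extend(weights[:-1])
        return fsum(costs)

    return extra, missing, one_side(bins_a, owner_b), one_side(bins_b, owner_a)


def occurrence_denominator(a: BinSet, b: BinSet, alpha: float) -> float:
    """Σ_A Σ_{c∈P} ℓ(c)^α + Σ_B Σ_{c∈Q} ℓ(c)^α — repeats count per copy."""
    return a.occurrence_weight(alpha) + b.occurrence_weight(alpha)


def build_result(
    alpha: float,
    extra: float,
    missing: float,
    splits: float,
    joins: float,
    denominator: float,
    matchings: tuple[FamilyMatching, ...] = (),
) -> ComparisonResult:
    total = extra + missing + splits + joins
    if denominator > 0.0:
        norm = lambda x: x / denominator  # noqa: E731
    else:
        # both sets empty: identical by convention, score 0
        norm = lambda x: 0.0  # noqa: E731
    return ComparisonResult(
        alpha=alpha,
        cost_extra=extra,
        cost_missing=missing,
        cost_splits=splits,
        cost_joins=joins,
        total=total,
        denominator=denominator,
        normalized_extra=norm(extra),
        normalized_missing=norm(missing),
        normalized_splits=norm(splits),
        normalized_joins=norm(joins),
        normalized_total=norm(total),
        matchings=matchings,
    )


def dissimilarity_no_repeats(a: BinSet, b: BinSet, alpha: float) -> ComparisonResult:
    """D_α and d_α for two repeat-free bin sets, with the four components.

    The left set plays the role of the prediction, the right set the role of
    the reference: ``extra`` is mass unique to the left, ``missing`` unique
    to the right, ``splits`` the refinement cost of the left bins and
    ``joins`` that of the right bins.
    """
    alpha = check_alpha(alpha)
    _owner_map(a), _owner_map(b)  # raise on repeats with a helpful message
    extra, missing, splits, joins = component_totals(a.bins, b.bins, a_b_lengths(a, b), alpha)
    return build_result(
        alpha, extra, missing, splits, joins, occurrence_denominator(a, b, alpha)
    )


def a_b_lengths(a: BinSet, b: BinSet) -> dict[str, int]:
    merged = dict(a.lengths)
    merged.update(b.lengths)
    return merged


def normalize(result: ComparisonResult, a: BinSet, b: BinSet) -> ComparisonResult:
    """Recompute the normalized fields of *result* from the given pair.

    The denominator is the per-occurrence weighted length of both sets
    (a contig in several bins contributes once per copy), taken after any
    minimum-length filtering so the score is self-consistent with the
    compared content.
    """
    return build_result(
        result.alpha,
        result.cost_extra,
        result.cost_missing,
        result.cost_splits,
        result.cost_joins,
        occurrence_denominator(a, b, result.alpha),
        result.matchings,
    )
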