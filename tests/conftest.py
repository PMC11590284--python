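import random

import pytest
from hypothesis import settings

from plascompare import BinSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_binset(bins: dict[str, set[str]], lengths: dict[str, int], label: str = "X") -> BinSet:
    return BinSet(label=label, bins={b: frozenset(c) for b, c in bins.items()}, lengths=lengths)


@pytest.fixture
def bs():
    """Factory fixture for terse BinSet construction in tests."""
    return make_binset


def random_repeat_instance(seed: int) -> tuple[BinSet, BinSet]:
    """A small random pair with up to 3 repeat families of up to 3 copies/side.

    Plain contigs appear at most once per side (on one or both sides);
    repeat contigs are placed in 0–3 distinct bins per side subject to
    k1 + k2 > 2, so every instance is within reach of the exhaustive oracle.
    """
    rng = random.Random(seed)
    n_bins_a = rng.randint(1, 4)
    # at least 3 bins overall so a family with k1 + k2 > 2 is placeable
    n_bins_b = rng.randint(max(1, 3 - n_bins_a), 4)
    a_bins: dict[str, set[str]] = {f"A{i}": set() for i in range(1, n_bins_a + 1)}
    b_bins: dict[str, set[str]] = {f"B{i}": set() for i in range(1, n_bins_b + 1)}
    lengths: dict[str, int] = {}

    for i in range(rng.randint(2, 6)):
        cid = f"p{i}"
        lengths[cid] = rng.randint(1, 100)
        side = rng.random()
        if side < 0.6:
            a_bins[rng.choice(sorted(a_bins))].add(cid)
            b_bins[rng.choice(sorted(b_bins))].add(cid)
        elif side < 0.8:
            a_bins[rng.choice(sorted(a_bins))].add(cid)
        else:
            b_bins[rng.choice(sorted(b_bins))].add(cid)

    for j in range(rng.randint(1, 3)):
        cid = f"r{j}"
        lengths[cid] = rng.randint(1, 100)
        while True:
            k1 = rng.randint(0, min(3, n_bins_a))
            k2 = rng.randint(0, min(3, n_bins_b))
            if k1 + k2 > 2:
                break
        for bid in rng.sample(sorted(a_bins), k1):
            a_bins[bid].add(cid)
        for bid in rng.sample(sorted(b_bins), k2):
            b_bins[bid].add(cid)

    def finish(label: str, bins: dict[str, set[str]]) -> BinSet:
        kept = {bid: frozenset(cs) for bid, cs in bins.items() if cs}
        if not kept:  # keep the pair comparable
            cid = f"{label}_pad"
            lengths[cid] = rng.randint(1, 100)
            kept = {f"{label}pad": frozenset({cid})}
        used = set().union(*kept.values())
        return BinSet(label=label, bins=kept, lengths={c: lengths[c] for c in used})

    return finish("left", a_bins), finish("right", b_bins)


def brute_force_refinement_cost(raw_weights: list[int], alpha: float) -> float:
    """Minimum total cost over all sequences of binary splits producing the parts.

    Parts are abstracted to their raw summed lengths; the cost of splitting
    a block of parts into two groups is min((Σ left)^α, (Σ right)^α), and
    every group is then split recursively until all parts stand alone.
    Exponential-time independent oracle for the closed form.
    """
    from functools import lru_cache

    n = len(raw_weights)

    @lru_cache(maxsize=None)
    def go(block: frozenset) -> float:
        if len(block) <= 1:
            return 0.0
        items = sorted(block)
        first, rest = items[0], items[1:]
        best = float("inf")
        for mask in range(2 ** len(rest)):
            left = frozenset({first} | {rest[i] for i in range(len(rest)) if mask >> i & 1})
            right = block - left
            if not right:
                continue
            w_left = sum(raw_weights[i] for i in left) ** alpha
            w_right = sum(raw_weights[i] for i in right) ** alpha
            best = min(best, min(w_left, w_right) + go(left) + go(right))
        return best

    return go(frozenset(range(n)))
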