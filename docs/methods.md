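# Methods

## The model

`plascompare` treats a plasmid bin as an unordered set of contig identifiers
and a bin assignment as a collection of such bins over a shared contig
universe with known lengths. The dissimilarity between two assignments is
the minimum cost of an edit scenario consisting of all bin **splits** first,
then all bin **joins** (mixed interleavings and translocations — exchanging
contig subsets between bins — are deliberately out of scope; the
splits-then-joins restriction is what makes the intermediate state, the
common refinement of the two assignments, unique and interpretable, and the
computation polynomial on repeat-free instances). Contigs present on only
one side are discarded up front, each contributing ℓ(c)^α.

Key facts the implementation relies on:

* **Closed-form refinement cost.** The cheapest split sequence producing
  parts P₁…P_k from their union detaches parts in increasing weight order,
  paying every part except the heaviest: Σᵢ L_α(Pᵢ) − maxᵢ L_α(Pᵢ). The test
  suite checks this against an exponential search over all binary split
  orders (memoised over part subsets, up to 6 parts).
* **Exact four-way decomposition.** extra + missing + splits + joins equals
  the total by construction; the same partition holds after normalization.
* **Normalization bounds.** d_α = D_α / (per-occurrence weight of both
  sides) is 0 iff the bin contents coincide and 1 iff the universes are
  disjoint. Component sums use `math.fsum`, so these bounds hold exactly in
  floating point regardless of iteration order.

## Repeats

A contig family needs resolution whenever some side holds ≥ 2 copies. The
classic criterion k₁ + k₂ > 2 misses the one-sided double (2, 0), which
still breaks the repeat-free precondition; its resolution is unique (empty
matching, both copies renamed apart), so including it costs nothing and
closes the gap. Matched copies share a fresh id `cid#i`; unmatched copies
get distinct `cid#j` ids and thus count as one-sided contigs. `#` is
rejected in user-supplied contig ids, so renames cannot collide.

The optimal resolution is found by depth-first branch-and-bound:

* **Family order**: descending matching count C(max,min)·min!, ties broken
  by descending contig length then id — the widest branching factor is
  fixed earliest so the bound prunes the largest subtrees.
* **Initial incumbent**: the identity-order resolution (i-th copy with i-th
  copy in sorted bin order) is evaluated before the search so pruning is
  active from the first node.
* **Bound**: a node is explored only if its partial dissimilarity is
  strictly below the incumbent; partial scores are monotone along
  root-to-leaf paths (optionally asserted at every edge via
  `check_bound=True`). Disabling pruning (`prune=False`) provably returns
  the same optimum and is exercised in tests.
* **Tie-break**: among equal-cost resolutions the incumbent found first in
  the deterministic enumeration order is kept, so reports are reproducible.

`exhaustive_dissimilarity` evaluates the full Cartesian product of
per-family matchings (capped at 10⁵ combinations) and serves purely as an
independent oracle; the randomized suite checks branch-and-bound equality on
hundreds of instances with up to 3 families of up to 3 copies per side.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| α | 0.5 | length-weight exponent; 0 counts edits, 1 weighs pure length. 0.5 penalises fragmentation of equal-length content that α = 1 cannot see |
| min length ℓ | 0 bp | contigs shorter than ℓ are dropped (and emptied bins removed) before family detection; short spurious contigs both add noise and inflate the branch-and-bound |
| min identity | 95 % | alignment filter for ground-truth construction; strictly lower hits are discarded |
| min coverage | 80 % | per-hit query coverage filter; an optional interval-union mode merges fragmented hits of one (query, subject) pair before the test |
| chromosome length | 500,000 bp | circular hybrid contigs strictly longer are chromosomes, strictly shorter are plasmids, non-circular are ambiguous; exactly 500 kbp is labelled plasmid and logged (half-megabase plasmids exist, half-megabase chromosomes do not) |

Normalization uses the *filtered* assignments, so a reported d_α is always
self-consistent with the content actually compared.

On the equal-length fragmentation example (a true bin of 2k equal contigs
vs. two half-bins, or vs. one half-bin plus k singletons), both predictions
tie at α = 1 and direct evaluation of the formulas above gives d₁ = 0.25;
the value 0.5 sometimes quoted for this construction corresponds to
normalizing by a single side's weight rather than both. The package asserts
the tie and the strict ordering for α < 1, which are the properties that
motivate α = 0.5, and records both numbers in the corresponding test.

## Degenerate inputs and numerics

* Two empty assignments score 0 (identical); exactly one empty scores 1
  (all mass one-sided). Precision/recall/F1 of two empty sets is 1 by
  convention (logged); against an empty opposite side the score is 0.
* F1 is the harmonic mean 2pr/(p+r), 0 when p + r = 0.
* Costs accumulate in double precision with `fsum`; component additivity is
  asserted at 1e-9 relative tolerance, the 0/1 bounds exactly.
* Within-bin duplicate rows in input TSVs are rejected (bins are sets, not
  multisets); an explicit dedupe flag collapses them with a warning.
* Ties for the heaviest refinement part are cost-neutral, so no tie-break
  is observable.

## Synthetic fixtures

The generator emulates the *combinatorial structure* of benchmark pairs: a
handful of bins (default 5) of 2–6 contigs with lengths uniform in
0.5–100 kbp (the span of typical plasmid-derived short-read contigs), and a
perturbation operator applying exact counts of the five edit kinds (drop,
add, duplicate-into-bin, split, join) in kind order with seeded choices,
returning a replayable log. It does not emulate sequence content, assembly
graphs, coverage, or the heavy-tailed contig-length and hit-noise
distributions of real assemblies — passing tests demonstrate the metric's
mathematical behaviour (bounds, symmetry, decomposition, exact optimality of
the search), not binning-tool performance on real data. Batch summaries use
the sample (n−1) standard deviation.

## Problem sizes

The default suite works at desk scale, chosen to exercise every code path
exactly: random repeat instances are capped at 3 families × 3 copies per
side (≤ 216 resolutions) so the exhaustive oracle stays cheap; property
suites run 100–210 seeded instances; the acceptance script scores
50 seeded bin sets per bound at three α values. Full-scale benchmarking of
real tools over dozens of genomes runs through the same `batch` entry point
and is limited only by the branch-and-bound on heavily repeated samples,
which the minimum-length filter is designed to tame.

## Known limitations

* The dissimilarity is not a metric in the mathematical sense (no triangle
  inequality is claimed), and allowing arbitrary split/join interleavings or
  translocations would yield lower scores on some instances.
* Branch-and-bound worst case is the product of per-family matching counts;
  families with many copies of one contig (large insertion-sequence load)
  may require a non-zero minimum length to stay tractable.
* Native output formats of specific binning tools are not parsed; users
  convert to the three-column TSV dialect.
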