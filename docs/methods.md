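# Methods

## Model and statistic

`wmwexact` computes the exact two-sided P value of the unpaired
two-sample Wilcoxon–Mann–Whitney rank-sum test. The pooled sample of
size N = m + n is sorted; tied values receive midranks (the arithmetic
mean of the 1-based positions the tied value occupies). With r(X) the
observed rank sum of group X, the permutation null is the set of all
C(N, m) group-label assignments of the pooled list, and

    P = min(1, 2 · min(π_r(X), π_r(Y)) / C(N, m)),

where π_r(X) counts size-m subsets of the pooled ranks with rank sum
lower than or equal to r(X), and π_r(Y) the size-n analogue. The raw
two-tail doubling can exceed 1 for balanced data, so P is capped at 1
(the conventional resolution). Both tail counts include the observed
group itself, so P > 0 always. One-sided tests, the U-statistic
formulation, paired tests and Hodges–Lehmann intervals are out of
scope.

## Exact integer arithmetic

Midranks of even-length tie runs are half-integers, so all ranks are
stored **doubled**: every DP key, threshold and rank sum is an exact
integer. Subset counts are arbitrary-precision integers (C(2000, 1000)
overflows any fixed-width type) and P is assembled as an exact
`fractions.Fraction`; conversion to float happens only when results are
rendered. Ties are decided by exact value equality after parsing —
callers who want fuzzy tying must pre-round.

## The dynamic program

The recursion π_S(k, i) = π_S(k, i−1) + π_{S−r_i}(k−1, i−1) is evaluated
iteratively from the smallest-ranked element forward. A layer is a map
from keys (subset size k, doubled rank sum s) to counts; consuming one
element sends each entry to the same key (element excluded) and to
(k+1, s+r) (element included), merging counts that meet at one key.
Only the current layer is kept.

Three refinements:

- **Pruning.** After each block, an entry (k, s) is removed if k > m, if
  k plus the number of unconsumed elements cannot reach m, or if s plus
  the sum of the smallest m−k remaining doubled ranks already exceeds
  the threshold. Entries completing at k = m are *tallied then
  retired*: counts with s ≤ threshold are added to the running tail
  tally and the entry is dropped either way. This bookkeeping keeps the
  tail count ≤-inclusive, consistent with the definition of π. Pruning
  is proven neutral in tests against completely unfiltered runs.
- **Tie blocks.** t elements sharing one midrank are absorbed in one
  step: entry (k, s) contributes count·C(t, j) at (k+j, s+j·r) for
  j = 0..t. The subtree spanned by t equal ranks is Pascal's triangle
  (t+1 distinct children rather than 2^t leaves); the binomial weight
  C(t, j) for all j is the only reading consistent with that structure
  and is verified entry-for-entry against t repeated single steps.
- **Tail orientation.** Exactly one group's rank sum lies at or below
  its null mean (doubled mean m(N+1) for size m). By default the DP
  counts that cheaper, heavily-pruned side at thresholds T and T−1 and
  obtains the opposite tail through the complement bijection S ↦ L∖S,
  which maps size-m subsets with doubled sum ≥ r(X) one-to-one onto
  size-n subsets with doubled sum ≤ r(Y); this is exact integer
  arithmetic, and tests assert bit-identity with the plain two-pass
  baseline (`two_pass=True`).

`count_tail` fuses the merge and prune passes (each child is filtered as
it is produced); tests assert it equals the explicit composition of the
public layer operations. The `workers` parameter partitions each
layer's key space into chunks whose partial maps merge by per-key
integer addition — an associative, commutative merge, so results are
bit-identical for any worker count. The partitions are processed
sequentially; the contract the package guarantees is determinism of the
partition-and-merge scheme, not a speedup, and a thread- or
process-based executor could be dropped in without changing any result.

Degenerate input (an empty group, non-finite values) is an error, not
P = 1: the statistic is undefined there.

## Normal approximation

For comparison the package ships the classical large-sample
approximation with midrank tie correction: W is the midrank sum of X,
E[W] = m(N+1)/2, Var[W] = mn/12·[(N+1) − Σ(t³−t)/(N(N−1))] over tie
runs, with an optional continuity correction subtracting 0.5 from
|W − E[W]|; the two-sided P is twice the upper normal tail, capped at 1.
This matches the documented default behaviour of mainstream statistics
software, and the implementation is cross-checked against an
independent one (scipy's asymptotic path) to 1e-12. Exact numerical
equality with any particular external package is deliberately not
asserted — dialects differ at the continuity boundary. If all pooled
values are tied the variance is zero; the result is flagged degenerate
with P = 1.

## Batch testing

`batch_test` runs one test per feature of a features × samples matrix
with a two-level group label. Missing cells are dropped per feature
(maximising per-feature power) rather than excluding samples globally;
approximate and exact P for a feature always use the identical subset.
Benjamini–Hochberg adjustment is applied across the successfully tested
features only — features left with an empty group are flagged and
excluded from the BH denominator, and the output says so. `bh_adjust`
delegates to statsmodels' step-up implementation and is verified
against an independent hand-written step-up oracle.

## Synthetic cohorts

Two generators define the simulation conditions used throughout the
tests:

- `gen_shifted_normal(m, n, shift, sd, seed)`: X ~ N(0, sd²),
  Y ~ N(shift, sd²). Continuous draws — tie-free almost surely —
  emulating expression-like measurements with a pure location shift and
  equal spread.
- `gen_categorical(m, n, k, probs, seed)`: integer codes 1..k per
  group, the heavy-ties regime (at most k tie runs regardless of
  cohort size); defaults to k = 4 uniform categories.

Both use one documented seedable generator (`numpy.random.default_rng`)
and are reproducible from the seed. What they do *not* emulate: unequal
group variances, correlated features, batch effects, non-location
alternatives, or realistic missingness patterns. Passing tests
therefore demonstrate correctness of the permutation computation and
calibration under clean location-shift and categorical nulls, not
robustness to those real-data complications — the exact test itself is,
of course, distribution-free.

## Tree instrumentation

`tree_stats(n_ranks, layers)` builds the **unpruned** dedup frontier on
untied integer ranks 1..N and records, per layer i, the distinct keys
stored versus the 2^i nodes of the full binary recursion tree, plus
cumulative sums (root included, so L layers correspond to 2^(L+1)−1
binary nodes). On untied ranks the closed forms

    distinct(i)   = (i+1) + C(i+1, 3)
    cumulative(L) = (L+1)(L+2)/2 + C(L+2, 4)

hold (size-j subsets of 1..i realise every sum in a contiguous range of
length j(i−j)+1) and are verified both against a brute-force subset
enumeration and against the frontier build. The headline numbers: 561
distinct keys stored through layer 10 versus 2047 binary nodes (72.59%
duplicates), the first duplicate appearing at layer 4, 99.64%
cumulative duplicates through layer 20, and 99.999% duplicates within
layer 28 alone. These are computed on the unpruned, untied tree:
pruning or tie merging would change the counts, and the statistic is
about raw key collapse.

## Problem sizes and numerical choices in the test suite

- Oracle equivalence: 500 random instances at N ≤ 12 against exhaustive
  enumeration (the enumeration guard refuses N > 22), exact rational
  equality.
- Type-I error: 1000 null cohorts at m = n = 20; the rejection fraction
  at α = 0.05 must not exceed 0.05 plus three binomial standard errors
  (the discrete exact test may only be conservative, never
  anticonservative).
- Approximation bias: cohorts at m = n = 15 with a 3σ shift; among
  instances with exact P < 1e-6 the approximation must exceed the exact
  P in a majority (it did in 40 of 40 on the fixed seed).
- Convergence of the approximation is checked at m = n = 10/20/40
  (median relative error over seven cohorts per size must decrease);
  these sizes keep the pure-Python DP comfortably fast while the trend
  is already unambiguous.
- Scalability: one m = n = 200 four-category cohort (N = 400, heavy
  ties) runs in a few seconds thanks to the tie-block merge, and its
  exact P agrees with the normal approximation within a factor of two,
  as expected at that size.

## Known limitations

- Pure Python: untied cohorts beyond a few hundred per group are slow
  (the tie-block shortcut does not apply); heavily tied cohorts scale
  much further.
- The CLI accepts comma-separated CSV with "." decimals only; missing
  tokens are the empty cell, "NA" and "NaN" (case-insensitive).
- P values are exact, but the test's discreteness means attainable
  significance levels are a finite set; at tiny N the minimum
  two-sided P is 2/C(N, m).
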