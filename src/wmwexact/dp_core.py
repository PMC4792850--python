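"""Exact permutation P value of the two-sample rank-sum test.

The two-sided exact P value compares the observed rank sum of each group
against all C(N, m) group-label permutations of the pooled list:

    P = min(1, 2 * min(pi_x, pi_y) / C(N, m))

where ``pi_x`` is the number of size-m subsets of the pooled ranks whose
rank sum is lower than or equal to the observed r(X), and likewise
``pi_y`` for Y.  The subsets are counted by a layered dynamic program
over keys ``(subset size k, doubled rank sum s)``: consuming one pooled
element maps every frontier entry to an "excluded" child (same key) and
an "included" child ``(k+1, s+rank)``, and recursion paths meeting at
the same key are merged by summing their counts.  Tie runs of length t
are absorbed in a single step with binomial weights C(t, j) — the
subtree spanned by t equal ranks is Pascal's triangle, so it contributes
only t+1 distinct children instead of 2^t leaves.  Pruning filters
discard entries that provably cannot complete into a counted subset.

All counts are arbitrary-precision integers and the P value is formed as
an exact :class:`fractions.Fraction`; floating point appears only at the
output boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from .ranks import RankedData, RankSums, build_ranked_data

__all__ = [
    "Frontier",
    "TailSpec",
    "ExactResult",
    "advance_layer",
    "merge_tie_block",
    "apply_prune_filters",
    "count_tail",
    "two_sided_p",
    "exact_wmw_p",
]


@dataclass
class Frontier:
    """One DP layer: map ``(k, s)`` -> subset count after ``layer_index`` elements.

    ``k`` is the subset size, ``s`` the doubled rank sum.  Without
    pruning the counts over all entries sum to ``2**layer_index``.
    """

    entries: dict
    layer_index: int = 0

    @classmethod
    def root(cls) -> "Frontier":
        return cls(entries={(0, 0): 1}, layer_index=0)

    def total_count(self) -> int:
        return sum(self.entries.values())


@dataclass
class TailSpec:
    """Parameters of one tail count.

    Attributes
    ----------
    size : int
        Target subset size (m or n).
    threshold2 : int
        Doubled rank-sum threshold (the observed doubled rank sum).
    tally : int
        Running count of completed subsets of that size with doubled
        rank sum <= threshold2.
    """

    size: int
    threshold2: int
    tally: int = 0


@dataclass(frozen=True)
class ExactResult:
    """Exact two-sided rank-sum test result."""

    count_x: int
    count_y: int
    total: int
    p_exact: Fraction
    p: float

    @property
    def p_fraction_str(self) -> str:
        return f"{self.p_exact.numerator}/{self.p_exact.denominator}"


def advance_layer(frontier: Frontier, rank2: int) -> Frontier:
    """Consume one pooled element of doubled rank ``rank2``.

    Every entry ``((k, s), c)`` contributes ``c`` at ``(k, s)`` (element
    excluded) and ``c`` at ``(k+1, s+rank2)`` (element included);
    contributions meeting at one key are summed.
    """
    if rank2 < 1:
        raise ValueError("rank2 must be a positive integer")
    new: dict = dict(frontier.entries)
    for (k, s), c in frontier.entries.items():
        key = (k + 1, s + rank2)
        new[key] = new.get(key, 0) + c
    return Frontier(entries=new, layer_index=frontier.layer_index + 1)


def merge_tie_block(frontier: Frontier, rank2: int, t: int) -> Frontier:
    """Absorb a run of ``t`` elements sharing doubled rank ``rank2`` in one step.

    Equivalent to ``t`` successive :func:`advance_layer` calls with the
    same rank: each entry ``((k, s), c)`` contributes ``c * C(t, j)`` at
    ``(k + j, s + j*rank2)`` for ``j = 0..t``.
    """
    if t < 1:
        raise ValueError("run length t must be >= 1")
    if rank2 < 1:
        raise ValueError("rank2 must be a positive integer")
    weights = [math.comb(t, j) for j in range(t + 1)]
    new: dict = {}
    for (k, s), c in frontier.entries.items():
        for j, w in enumerate(weights):
            key = (k + j, s + j * rank2)
            new[key] = new.get(key, 0) + w * c
    return Frontier(entries=new, layer_index=frontier.layer_index + t)


def apply_prune_filters(
    frontier: Frontier,
    i: int,
    tail: TailSpec,
    remaining_ranks2: Sequence[int],
) -> Frontier:
    """Drop frontier entries that cannot contribute to ``tail``.

    With ``m = tail.size`` and ``i`` pooled elements consumed, an entry
    ``(k, s)`` is removed when (1) ``k > m``; (2) ``k + (N - i) < m``
    (too few elements left to reach size m); (3) ``s`` plus the sum of
    the smallest ``m - k`` remaining doubled ranks already exceeds the
    threshold.  Entries that have completed (``k == m``) are retired:
    those with ``s <= threshold2`` are added to ``tail.tally`` first.

    ``remaining_ranks2`` must hold the doubled ranks not yet consumed,
    ascending.  ``tail`` is updated in place; a pruned frontier is
    returned.
    """
    m = tail.size
    thr = tail.threshold2
    n_rem = len(remaining_ranks2)
    # prefix[j] = sum of the j smallest remaining doubled ranks
    prefix = [0] * (n_rem + 1)
    for j, r in enumerate(remaining_ranks2):
        prefix[j + 1] = prefix[j] + r
    kept: dict = {}
    for (k, s), c in frontier.entries.items():
        if k > m:
            continue
        if k == m:
            if s <= thr:
                tail.tally += c
            continue
        need = m - k
        if need > n_rem:
            continue
        if s + prefix[need] > thr:
            continue
        kept[(k, s)] = c
    return Frontier(entries=kept, layer_index=frontier.layer_index)


def _chunks(items: list, workers: int):
    if workers <= 1 or len(items) <= 1:
        yield items
        return
    step = (len(items) + workers - 1) // workers
    for a in range(0, len(items), step):
        yield items[a : a + step]


def _expand_run(
    chunk,
    r2: int,
    weights: Sequence[int],
    size: int,
    thr: int,
    i_new: int,
    n_total: int,
    prefix: Sequence[int],
):
    """Expand one frontier chunk through a tie run, pruning as we go.

    Returns a partial (packed-key) frontier and a partial tally of
    completed subsets.  Merging partial results is per-key integer
    addition, so any partition of the chunk gives identical totals.
    """
    out: dict = {}
    tally = 0
    get = out.get
    for key, c, k, s in chunk:
        jmax = min(len(weights) - 1, size - k)
        for j in range(jmax + 1):
            s2 = s + j * r2
            if s2 > thr:
                break
            k2 = k + j
            if k2 == size:
                tally += weights[j] * c
                continue
            need = size - k2
            if i_new + need > n_total:
                continue
            if s2 + prefix[i_new + need] - prefix[i_new] > thr:
                continue
            key2 = (k2, s2)
            out[key2] = get(key2, 0) + weights[j] * c
    return out, tally


def count_tail(data: RankedData, tail: TailSpec, workers: int = 1) -> int:
    """Number of size-``tail.size`` subsets of the pooled doubled ranks
    with doubled rank sum <= ``tail.threshold2``.

    Iterates one merge step per tie run with pruning applied to every
    child as it is produced (fusing the merge and filter passes); the
    result is identical to running :func:`merge_tie_block` followed by
    :func:`apply_prune_filters` block by block.  ``workers`` partitions
    each layer's key space; partial maps merge by per-key addition, so
    the result is independent of the worker count.
    """
    size = tail.size
    thr = tail.threshold2
    if not (1 <= size <= data.total):
        raise ValueError("tail size must be between 1 and N")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    n_total = data.total
    prefix = [0] * (n_total + 1)
    for j, r in enumerate(data.ranks2):
        prefix[j + 1] = prefix[j] + r

    cur: dict = {(0, 0): 1}
    tally = 0
    i = 0
    for r2, t in data.tie_runs:
        i_new = i + t
        weights = [math.comb(t, j) for j in range(t + 1)]
        items = [(key, c, key[0], key[1]) for key, c in cur.items()]
        merged: dict = {}
        for chunk in _chunks(items, workers):
            part, part_tally = _expand_run(
                chunk, r2, weights, size, thr, i_new, n_total, prefix
            )
            tally += part_tally
            if not merged:
                merged = part
            else:
                get = merged.get
                for key, c in part.items():
                    merged[key] = get(key, 0) + c
        cur = merged
        i = i_new
        if not cur:
            break
    tail.tally = tally
    return tally


def two_sided_p(count_x: int, count_y: int, total: int) -> Fraction:
    """Two-sided exact P: ``min(1, 2 * min(count_x, count_y) / total)``."""
    if total <= 0:
        raise ValueError("total permutation count must be positive")
    if not (1 <= count_x <= total and 1 <= count_y <= total):
        raise ValueError("tail counts must lie in [1, total]")
    p = Fraction(2 * min(count_x, count_y), total)
    return min(p, Fraction(1))


def exact_wmw_p(
    x: Sequence[float],
    y: Sequence[float],
    workers: int = 1,
    two_pass: bool = False,
) -> ExactResult:
    """Exact two-sided rank-sum test of samples ``x`` and ``y``.

    The result is symmetric in the argument order and invariant under
    any strictly increasing transform of the values (the test is
    rank-based).  Ties are handled exactly via midranks; no continuity
    or tie correction is involved.

    Parameters
    ----------
    x, y : sequences of finite numbers
        The two sample groups; both must be non-empty.
    workers : int
        Partition count for each DP layer; the result is bit-identical
        for any value.
    two_pass : bool
        If True, run one independent DP pass per tail.  The default
        counts only the tail whose threshold lies at or below its null
        mean (the cheaper, more heavily pruned orientation) at
        thresholds T and T-1 and derives the opposite tail through the
        complement bijection S -> L\\S, which maps size-m subsets with
        doubled sum >= r(X) one-to-one onto size-n subsets with doubled
        sum <= r(Y).  Both strategies give identical integers.
    """
    data, sums = build_ranked_data(x, y)
    m, n = data.m, data.n
    big_n = data.total
    total = math.comb(big_n, m)

    if two_pass:
        count_x = count_tail(data, TailSpec(size=m, threshold2=sums.rX2), workers)
        count_y = count_tail(data, TailSpec(size=n, threshold2=sums.rY2), workers)
    else:
        # Exactly one group sits at or below its null mean rank sum
        # (doubled mean for size m is m*(N+1)); count that side.
        if sums.rX2 - m * (big_n + 1) <= sums.rY2 - n * (big_n + 1):
            size, thr = m, sums.rX2
            x_is_base = True
        else:
            size, thr = n, sums.rY2
            x_is_base = False
        c_le = count_tail(data, TailSpec(size=size, threshold2=thr), workers)
        c_lt = count_tail(data, TailSpec(size=size, threshold2=thr - 1), workers)
        c_other = total - c_lt
        count_x, count_y = (c_le, c_other) if x_is_base else (c_other, c_le)

    p_exact = two_sided_p(count_x, count_y, total)
    return ExactResult(
        count_x=count_x,
        count_y=count_y,
        total=total,
        p_exact=p_exact,
        p=float(p_exact),
    )
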