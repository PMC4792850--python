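"""Brute-force reference for the exact rank-sum test.

Deliberately naive: enumerates all C(N, m) group-label assignments of
the pooled list by index combinations, so tied values are treated
exactly as the dynamic program treats them.  Used as the correctness
oracle in tests; guarded to small N.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations
from typing import Sequence

from .dp_core import ExactResult, two_sided_p
from .ranks import RankedData, build_ranked_data

__all__ = ["brute_force_tail", "brute_force_p", "MAX_N"]

MAX_N = 22


def _guard(n_total: int) -> None:
    if n_total > MAX_N:
        raise ValueError(f"enumeration oracle refuses N={n_total} > {MAX_N}")


def brute_force_tail(data: RankedData, size: int, threshold2: int) -> int:
    """Count size-``size`` index subsets of the pooled doubled ranks with
    doubled rank sum <= ``threshold2``, by explicit enumeration."""
    _guard(data.total)
    count = 0
    for combo in combinations(data.ranks2, size):
        if sum(combo) <= threshold2:
            count += 1
    return count


def brute_force_p(x: Sequence[float], y: Sequence[float]) -> ExactResult:
    """Exact two-sided rank-sum P by exhaustive enumeration (N <= 22)."""
    data, sums = build_ranked_data(x, y)
    _guard(data.total)
    count_x = brute_force_tail(data, data.m, sums.rX2)
    count_y = brute_force_tail(data, data.n, sums.rY2)
    total = math.comb(data.total, data.m)
    p_exact = two_sided_p(count_x, count_y, total)
    return ExactResult(
        count_x=count_x,
        count_y=count_y,
        total=total,
        p_exact=p_exact,
        p=float(p_exact),
    )
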