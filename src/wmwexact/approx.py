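"""Tie-corrected normal approximation to the rank-sum test.

This is the classical large-sample approximation that mainstream
statistics packages apply by default when ties are present, provided
here for side-by-side reporting against the exact permutation P.  With
W the midrank sum of group X,

    E[W]   = m (N + 1) / 2
    Var[W] = m n / 12 * [ (N + 1) - sum_j (t_j^3 - t_j) / (N (N - 1)) ]

summing over tie runs of length t_j.  The continuity correction
subtracts 0.5 from |W - E[W]| before standardising; the two-sided P is
twice the upper normal tail of |z|, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm

from .ranks import build_ranked_data

__all__ = ["ApproxResult", "normal_approx_p"]


@dataclass(frozen=True)
class ApproxResult:
    z: float
    p: float
    continuity: bool
    tie_correction_term: int
    degenerate: bool = False  # all values tied: zero variance, p := 1


def normal_approx_p(
    x: Sequence[float], y: Sequence[float], continuity: bool = True
) -> ApproxResult:
    """Two-sided normal-approximation P for samples ``x`` and ``y``."""
    data, sums = build_ranked_data(x, y)
    m, n = data.m, data.n
    big_n = data.total
    tie_term = sum(t**3 - t for _, t in data.tie_runs)

    w = sums.rX2 / 2.0
    mean = m * (big_n + 1) / 2.0
    if big_n < 2:
        raise ValueError("need at least two pooled observations")
    var = m * n / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1.0)))
    if var <= 0.0:
        return ApproxResult(
            z=0.0,
            p=1.0,
            continuity=continuity,
            tie_correction_term=tie_term,
            degenerate=True,
        )
    dev = abs(w - mean)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z_abs = dev / math.sqrt(var)
    z = math.copysign(z_abs, w - mean) if w != mean else 0.0
    p = min(1.0, 2.0 * norm.sf(z_abs))
    return ApproxResult(
        z=z, p=p, continuity=continuity, tie_correction_term=tie_term
    )
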