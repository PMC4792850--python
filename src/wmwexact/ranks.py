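"""Pooled ranking for the two-sample rank-sum test.

Two raw samples are pooled, sorted and midranked.  Midranks of tied
elements are the arithmetic mean of the 1-based positions the tied value
occupies; because a tie run of even length produces half-integer
midranks, every rank in this package is stored *doubled* so that all
downstream rank-sum arithmetic is exact integer arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = ["RankedData", "RankSums", "assign_midranks", "build_ranked_data"]


@dataclass(frozen=True)
class RankedData:
    """Pooled, sorted, labelled and midranked two-sample data.

    Attributes
    ----------
    values : tuple
        Pooled values in ascending order, length ``N = m + n``.
    labels : tuple of str
        Group indicator ("X" or "Y") per pooled element.
    ranks2 : tuple of int
        Doubled midrank per pooled element (2, 4, ..., 2N when untied).
    tie_runs : tuple of (int, int)
        ``(doubled rank, run length)`` per maximal tie run, in rank order.
    m, n : int
        Group sizes of X and Y.
    """

    values: tuple
    labels: tuple
    ranks2: tuple
    tie_runs: tuple
    m: int
    n: int

    @property
    def total(self) -> int:
        return self.m + self.n

    @property
    def has_ties(self) -> bool:
        return any(t > 1 for _, t in self.tie_runs)


@dataclass(frozen=True)
class RankSums:
    """Observed doubled rank sums of the two groups (rX2 + rY2 = N(N+1))."""

    rX2: int
    rY2: int


def _check_finite(values: Sequence[float]) -> None:
    for i, v in enumerate(values):
        if not math.isfinite(v):
            raise ValueError(f"non-finite value at position {i}: {v!r}")


def assign_midranks(values: Sequence[float]) -> list[int]:
    """Doubled midranks of ``values``, returned in input order.

    Element ``i`` receives twice the mean of the 1-based positions its
    value occupies in the sorted list; ties are decided by exact value
    equality (callers wanting fuzzy tying must pre-round).

    >>> assign_midranks([3, 1, 4, 1, 5])
    [6, 3, 8, 3, 10]
    """
    if len(values) == 0:
        raise ValueError("cannot rank an empty list")
    _check_finite(values)
    order = sorted(range(len(values)), key=values.__getitem__)
    n = len(values)
    ranks2 = [0] * n
    i = 0
    while i < n:
        j = i
        v = values[order[i]]
        while j + 1 < n and values[order[j + 1]] == v:
            j += 1
        # positions i+1 .. j+1 (1-based); doubled mean = (i+1) + (j+1)
        r2 = i + j + 2
        for t in range(i, j + 1):
            ranks2[order[t]] = r2
        i = j + 1
    return ranks2


def build_ranked_data(
    x: Sequence[float], y: Sequence[float]
) -> tuple[RankedData, RankSums]:
    """Pool two samples into a :class:`RankedData` plus observed rank sums.

    Sorting is stable; label order within a tie run does not affect any
    downstream quantity (ranks within a run are equal by construction).
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    _check_finite(x)
    _check_finite(y)
    pooled = [(v, "X") for v in x] + [(v, "Y") for v in y]
    pooled.sort(key=lambda p: p[0])
    values = tuple(p[0] for p in pooled)
    labels = tuple(p[1] for p in pooled)
    ranks2 = tuple(assign_midranks(list(values)))

    tie_runs = []
    i = 0
    n_tot = len(values)
    while i < n_tot:
        j = i
        while j + 1 < n_tot and values[j + 1] == values[i]:
            j += 1
        tie_runs.append((ranks2[i], j - i + 1))
        i = j + 1

    rX2 = sum(r for r, lab in zip(ranks2, labels) if lab == "X")
    rY2 = sum(r for r, lab in zip(ranks2, labels) if lab == "Y")
    data = RankedData(
        values=values,
        labels=labels,
        ranks2=ranks2,
        tie_runs=tuple(tie_runs),
        m=len(x),
        n=len(y),
    )
    return data, RankSums(rX2=rX2, rY2=rY2)
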