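"""Synthetic cohorts and DP-tree instrumentation.

Two generators emulate the data regimes the exact test is aimed at:
shifted-normal cohorts (continuous, essentially tie-free) and
integer-coded categorical cohorts with few levels (heavily tied, the
regime where the tie-block merge pays off).  ``tree_stats`` instruments
the growth of the deduplicating DP frontier itself, quantifying how many
nodes of the conceptual full binary recursion tree collapse onto shared
(subset size, rank sum) keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dp_core import Frontier, advance_layer

__all__ = [
    "TreeStats",
    "gen_shifted_normal",
    "gen_categorical",
    "tree_stats",
    "distinct_keys_untied",
    "cumulative_distinct_untied",
]


@dataclass(frozen=True)
class TreeStats:
    """Per-layer and cumulative key statistics of the unpruned DP tree.

    Layer 0 is the root.  ``binary_nodes[i] = 2**i`` is the size layer i
    would have in the full binary recursion tree; ``duplicates[i]`` is
    how many of those nodes collapse onto already-present keys.
    """

    layers: list
    distinct_keys: list
    binary_nodes: list
    duplicates: list
    cum_distinct: list
    cum_binary: list
    cum_duplicates: list

    def duplicate_fraction(self, i: int) -> float:
        """Fraction of layer i's binary nodes that are duplicates."""
        return self.duplicates[i] / self.binary_nodes[i]

    def cum_duplicate_fraction(self, i: int) -> float:
        """Duplicate fraction over all nodes from the root through layer i."""
        return self.cum_duplicates[i] / self.cum_binary[i]


def gen_shifted_normal(
    m: int, n: int, shift: float, sd: float = 1.0, seed=None
) -> tuple[list, list]:
    """Two normal cohorts: X ~ N(0, sd), Y ~ N(shift, sd).

    Continuous draws, so ties are absent almost surely; reproducible
    from ``seed``.
    """
    if m < 1 or n < 1:
        raise ValueError("group sizes must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, sd, size=m)
    y = rng.normal(shift, sd, size=n)
    return [float(v) for v in x], [float(v) for v in y]


def gen_categorical(
    m: int,
    n: int,
    k: int,
    probs_x=None,
    probs_y=None,
    seed=None,
) -> tuple[list, list]:
    """Two integer-coded categorical cohorts with values in 1..k.

    With k small relative to m + n the pooled data contain at most k tie
    runs, the heavy-ties regime.  ``probs_x``/``probs_y`` default to
    uniform.
    """
    if k < 2:
        raise ValueError("need at least two categories")
    if m < 1 or n < 1:
        raise ValueError("group sizes must be >= 1")

    def _probs(p):
        if p is None:
            return np.full(k, 1.0 / k)
        p = np.asarray(p, dtype=float)
        if p.shape != (k,) or np.any(p < 0) or not math.isclose(p.sum(), 1.0):
            raise ValueError("probabilities must be length-k, >= 0, sum to 1")
        return p / p.sum()

    rng = np.random.default_rng(seed)
    cats = np.arange(1, k + 1)
    x = rng.choice(cats, size=m, p=_probs(probs_x))
    y = rng.choice(cats, size=n, p=_probs(probs_y))
    return [int(v) for v in x], [int(v) for v in y]


def distinct_keys_untied(i: int) -> int:
    """Closed form for the distinct keys at layer i on untied ranks.

    After consuming untied ranks 1..i, subsets of size j realise every
    sum between j(j+1)/2 and j(2i-j+1)/2, giving j(i-j)+1 keys; summing
    over j yields (i+1) + C(i+1, 3).
    """
    return (i + 1) + math.comb(i + 1, 3)


def cumulative_distinct_untied(layers: int) -> int:
    """Closed-form sum of :func:`distinct_keys_untied` over layers 0..L."""
    return (layers + 1) * (layers + 2) // 2 + math.comb(layers + 2, 4)


def tree_stats(n_ranks: int, layers: int) -> TreeStats:
    """Instrument the unpruned dedup DP frontier on untied ranks 1..n_ranks.

    Builds the frontier one element at a time (no pruning, no tie
    merging — the ranks are untied) and records, per layer 0..layers,
    the number of distinct keys actually stored against the ``2**i``
    nodes of the full binary recursion tree, plus cumulative sums.
    """
    if layers > n_ranks:
        raise ValueError("layers cannot exceed the number of ranks")
    if n_ranks < 1:
        raise ValueError("need at least one rank")
    frontier = Frontier.root()
    distinct = [len(frontier.entries)]
    for i in range(1, layers + 1):
        frontier = advance_layer(frontier, 2 * i)  # doubled untied rank i
        distinct.append(len(frontier.entries))
    idx = list(range(layers + 1))
    binary = [2**i for i in idx]
    dups = [b - d for b, d in zip(binary, distinct)]
    cum_d = list(np.cumsum(distinct).astype(object))
    cum_b = [2 ** (i + 1) - 1 for i in idx]
    cum_dup = [b - d for b, d in zip(cum_b, cum_d)]
    return TreeStats(
        layers=idx,
        distinct_keys=distinct,
        binary_nodes=binary,
        duplicates=dups,
        cum_distinct=[int(v) for v in cum_d],
        cum_binary=cum_b,
        cum_duplicates=[int(v) for v in cum_dup],
    )
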