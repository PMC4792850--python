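"""Batch testing of a feature matrix with false-discovery-rate control.

Mirrors the biomarker-panel workflow: each feature (e.g., a miRNA) of a
features x samples matrix is tested between two sample groups, missing
values are dropped per feature, and the exact P values are adjusted
across the panel with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .approx import normal_approx_p
from .dp_core import exact_wmw_p

__all__ = ["FeatureTable", "bh_adjust", "batch_test"]


@dataclass
class FeatureTable:
    """Features x samples matrix with a two-level group label per sample.

    ``matrix`` is float-valued with NaN marking missing cells.
    """

    feature_ids: list
    matrix: np.ndarray
    groups: list

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.feature_ids), len(self.groups)):
            raise ValueError("matrix shape must be (n_features, n_samples)")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        levels = sorted(set(self.groups))
        if len(levels) != 2:
            raise ValueError(
                f"exactly two group levels required, got {levels!r}"
            )

    @property
    def levels(self) -> tuple:
        return tuple(sorted(set(self.groups)))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P values (order-preserving).

    Input values must lie in (0, 1]; output is elementwise >= input and
    capped at 1.
    """
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("P values must lie in (0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def batch_test(
    table: FeatureTable,
    mode: str = "both",
    continuity: bool = True,
    adjust: bool = True,
    workers: int = 1,
) -> pd.DataFrame:
    """Test every feature of ``table`` between the two groups.

    Missing cells are dropped per feature, so each feature is tested on
    its own complete subset of samples (approximate and exact P for a
    feature always use the identical subset).  Features left with an
    empty group are flagged in ``status`` and excluded from the BH
    denominator.

    Returns a DataFrame indexed by feature with columns ``n_x``,
    ``n_y``, ``ties_present``, ``p_exact`` and/or ``p_approx``,
    ``p_exact_num``/``p_exact_den`` (the exact fraction), ``q`` (BH on
    the exact — or sole — P column) and ``status``.
    """
    if mode not in ("exact", "approx", "both"):
        raise ValueError("mode must be 'exact', 'approx' or 'both'")
    lev_x, lev_y = table.levels
    groups = np.asarray(table.groups)
    rows = []
    for fid, row in zip(table.feature_ids, table.matrix):
        keep = np.isfinite(row)
        x = row[keep & (groups == lev_x)]
        y = row[keep & (groups == lev_y)]
        rec: dict = {
            "feature": fid,
            "n_x": len(x),
            "n_y": len(y),
            "status": "ok",
        }
        if len(x) == 0 or len(y) == 0:
            rec["status"] = "empty_group"
            rec["ties_present"] = np.nan
            rows.append(rec)
            continue
        pooled = np.concatenate([x, y])
        rec["ties_present"] = len(np.unique(pooled)) < len(pooled)
        if mode in ("exact", "both"):
            res = exact_wmw_p(list(x), list(y), workers=workers)
            rec["p_exact"] = res.p
            rec["p_exact_num"] = res.p_exact.numerator
            rec["p_exact_den"] = res.p_exact.denominator
        if mode in ("approx", "both"):
            rec["p_approx"] = normal_approx_p(
                list(x), list(y), continuity=continuity
            ).p
        rows.append(rec)

    out = pd.DataFrame(rows).set_index("feature")
    if adjust:
        pcol = "p_exact" if mode in ("exact", "both") else "p_approx"
        out["q"] = np.nan
        ok = out["status"] == "ok"
        if ok.any():
            out.loc[ok, "q"] = bh_adjust(out.loc[ok, pcol].tolist())
    return out
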