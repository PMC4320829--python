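"""Per-age, per-feature group comparison: Mann-Whitney + FDR stars."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from meadev.features import FEATURE_NAMES

__all__ = ["mann_whitney", "fdr_adjust", "comparison_table"]

#: Largest combined sample size for which the exact null is enumerated.
EXACT_N_MAX = 20


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) test.

    The exact null distribution is used when the combined sample size
    is at most 20 and there are no ties; otherwise the normal
    approximation with midranks, tie-corrected variance and continuity
    correction.  Returns ``(U, p)`` where U counts pairs won by ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_N_MAX and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    With p sorted ascending, ``p_adj(i) = min_{j >= i} min(1, m p(j)/j)``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def _stars(p_adj: float, alpha: tuple[float, float] = (0.05, 0.01)) -> str:
    if math.isnan(p_adj):
        return ""
    if p_adj < alpha[1]:
        return "**"
    if p_adj < alpha[0]:
        return "*"
    return "ns"


def comparison_table(
    features: pd.DataFrame,
    feature_names=FEATURE_NAMES,
    family: str = "pooled",
    group_column: str = "region",
    groups: tuple[str, str] = ("CTX", "HPC"),
) -> pd.DataFrame:
    """Mann-Whitney comparison of two groups per (feature, age) cell.

    Undefined (NaN) feature values are dropped before testing; the
    ``n_ctx``/``n_hpc`` columns report post-drop sizes.  Cells missing
    a group, or with fewer than two values in either group, carry an
    undefined test (NaN U and p).  FDR correction pools all defined
    tests by default (``family="pooled"``); ``family="per_feature"``
    corrects within each feature's set of ages instead.
    """
    if family not in ("pooled", "per_feature"):
        raise ValueError(f"unknown family rule {family!r}")
    rows = []
    for feat in feature_names:
        for age in sorted(features["age_div"].unique()):
            sub = features[features["age_div"] == age]
            x = sub.loc[sub[group_column] == groups[0], feat].dropna().to_numpy()
            y = sub.loc[sub[group_column] == groups[1], feat].dropna().to_numpy()
            if x.size >= 2 and y.size >= 2:
                u, p = mann_whitney(x, y)
            else:
                u, p = math.nan, math.nan
            rows.append(
                {
                    "feature": feat,
                    "age_div": age,
                    "n_ctx": int(x.size),
                    "n_hpc": int(y.size),
                    "U": u,
                    "p_raw": p,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    if family == "pooled":
        mask = table["p_raw"].notna()
        if mask.any():
            table.loc[mask, "p_adjusted"] = fdr_adjust(table.loc[mask, "p_raw"].to_numpy())
    else:
        for feat in feature_names:
            mask = (table["feature"] == feat) & table["p_raw"].notna()
            if mask.any():
                table.loc[mask, "p_adjusted"] = fdr_adjust(table.loc[mask, "p_raw"].to_numpy())
    table["significance"] = [_stars(p) for p in table["p_adjusted"]]
    return table
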