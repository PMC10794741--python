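"""Pearson screening of plot features against FDI, per cultivar group.

Every feature is correlated with the frost damage index separately within
three groups — ALL plots, GREEN cultivars, RED cultivars — and kept when its
two-sided p-value is below alpha (0.01, "highly significant").  The p < alpha
rule is equivalent to an absolute-r threshold

    r_crit = t_crit / sqrt(t_crit^2 + n - 2),   t_crit = t(1 - alpha/2, n - 2),

which is recomputed from each feature's usable sample size (missing values
are deleted pairwise, so denominator-degenerate index values never discard a
whole plot).  No multiple-testing correction is applied by default, matching
the per-feature screening convention; a Bonferroni option exists.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("ALL", "GREEN", "RED")

__all__ = ["GROUPS", "pearson_r", "critical_r", "select_features"]


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p after pairwise missing-value removal.

    The p-value comes from the exact t transform
    ``t = r sqrt((n-2) / (1-r^2))`` with ``n-2`` degrees of freedom.
    Raises on zero variance or fewer than 3 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def critical_r(n: int, alpha: float = 0.01) -> float:
    """|r| at which the two-sided p equals alpha for sample size n."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(t_crit**2 + n - 2))


def select_features(
    table: pd.DataFrame,
    alpha: float = 0.01,
    feature_cols: list[str] | None = None,
    target_col: str = "fdi",
    color_col: str = "cultivar_color",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Screen every feature in every group.

    ``table`` holds one row per plot with the target, the cultivar color and
    the feature columns (every column that is none of plot_id/target/color by
    default).  Returns one row per (group, feature) with ``n``, ``r``, ``p``,
    ``r_critical``, ``selected`` and a ``status`` flag (``ok``,
    ``zero_variance`` or ``insufficient_n``); non-``ok`` features are never
    selected.  Groups smaller than 3 plots are skipped.
    """
    if feature_cols is None:
        feature_cols = [
            c for c in table.columns
            if c not in ("plot_id", target_col, color_col)
        ]
    m = len(feature_cols)
    eff_alpha = alpha / m if bonferroni else alpha

    frames = {"ALL": table}
    for color, sub in table.groupby(color_col, observed=True):
        frames[str(color).upper()] = sub

    rows = []
    for group in GROUPS:
        sub = frames.get(group)
        if sub is None or len(sub) < 3:
            continue
        y = sub[target_col].to_numpy(dtype=float)
        for feat in feature_cols:
            x = sub[feat].to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y))
            n = int(keep.sum())
            rec = {
                "group": group, "feature": feat, "n": n,
                "r": np.nan, "p": np.nan, "r_critical": np.nan,
                "selected": False, "status": "ok",
            }
            if n < 3:
                rec["status"] = "insufficient_n"
            elif np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
                rec["status"] = "zero_variance"
            else:
                r, p = pearson_r(x, y)
                rc = critical_r(n, eff_alpha)
                rec.update(r=r, p=p, r_critical=rc, selected=bool(abs(r) > rc))
            rows.append(rec)
    return pd.DataFrame(rows)
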