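"""Frost damage index (FDI) from per-plot damage-grade counts.

Field surveys grade every plant in a breeding plot on an ordinal damage scale
0..MAX_DL (0 = undamaged).  The plot-level frost damage index is the weighted
mean grade normalized by the maximum grade,

    FDI = sum_i (PN_i * i) / (MAX_DL * TPN),

where ``PN_i`` is the number of plants at level ``i`` and ``TPN`` the total
plant count of the plot.  FDI lies in [0, 1]; it equals the mean per-plant
level divided by MAX_DL.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

LEVEL_PREFIX = "level_"

__all__ = ["LEVEL_PREFIX", "level_columns", "compute_fdi"]


def level_columns(table: pd.DataFrame) -> list[str]:
    """Grade-count columns ``level_0 .. level_MAX`` in level order."""
    pat = re.compile(rf"^{LEVEL_PREFIX}(\d+)$")
    cols = [(int(m.group(1)), c) for c in table.columns if (m := pat.match(c))]
    if not cols:
        raise ValueError("no 'level_<i>' grade-count columns found")
    cols.sort()
    levels = [lv for lv, _ in cols]
    if levels != list(range(len(levels))):
        raise ValueError(f"level columns must be contiguous from 0, got {levels}")
    return [c for _, c in cols]


def compute_fdi(
    table: pd.DataFrame, max_damage_level: int | None = None
) -> pd.DataFrame:
    """Per-plot FDI from a damage-grade table.

    Parameters
    ----------
    table
        One row per plot with a ``plot_id`` column and plant counts in
        ``level_0 .. level_<MAX_DL>`` columns.
    max_damage_level
        Normalizing maximum grade. Defaults to the highest level column
        present; may be set larger when the worst grade did not occur in
        the field.

    Returns
    -------
    DataFrame with columns ``plot_id`` and ``fdi``.
    """
    cols = level_columns(table)
    n_levels = len(cols)
    max_dl = max_damage_level if max_damage_level is not None else n_levels - 1
    if max_dl < 1:
        raise ValueError("max_damage_level must be >= 1")
    if max_dl < n_levels - 1:
        raise ValueError(
            f"max_damage_level={max_dl} below highest level column {n_levels - 1}"
        )

    counts = table[cols].to_numpy(dtype=float)
    if np.isnan(counts).any():
        raise ValueError("grade counts contain NaN")
    if (counts < 0).any():
        raise ValueError("grade counts must be non-negative")

    tpn = counts.sum(axis=1)
    if (tpn == 0).any():
        bad = table.loc[tpn == 0, "plot_id"].tolist()
        raise ValueError(f"plots with zero plants (FDI undefined): {bad}")

    levels = np.arange(n_levels, dtype=float)
    fdi = counts @ levels / (max_dl * tpn)
    return pd.DataFrame({"plot_id": table["plot_id"].to_numpy(), "fdi": fdi})
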