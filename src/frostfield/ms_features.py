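"""Multispectral features per plot: 5 band reflectances + 23 vegetation indexes.

Bands are the reflectances at 475 (blue), 560 (green), 668 (red), 717 (red
edge) and 840 nm (NIR).  The vegetation indexes cover the canonical
chlorophyll/structure set (NDVI, SR, EVI, ARVI, red-edge and pigment indexes)
and the four frost-damage indexes FD_VI1..FD_VI4, which extend an NDVI-like
normalized difference with the red-edge, green and blue bands plus additive
constants:

    FD_VI1 = (R840 + R717 - R668) / (R840 + R717 + R668)
    FD_VI2 = (R840 + R717 - R668) / (R840 + R717 + R668 - R475)
    FD_VI3 = (R840 + R717 - R668) / (R840 + R717 + 6 R668 - 7.5 R475 + 25)
    FD_VI4 = (R840 + R717 + R560 - R668) / (R840 + R717 + R668 + R560 - R475 + 7)

All formulas are evaluated verbatim on reflectance in [0, 1]; zero
denominators yield NaN (flagged missing), never an exception.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .imaging import PlotPixelSet

BAND_NAMES = ["R475", "R560", "R668", "R717", "R840"]
VI_NAMES = [
    "FD_VI1", "FD_VI2", "FD_VI3", "FD_VI4",
    "NDVI", "SR", "EVI", "ARVI", "RENDVI", "mSR", "mNDVI", "RERVI",
    "PRI", "SIPI", "RG", "PSRI", "CRI1", "CRI2", "ARI1", "ARI2",
    "GNDVI", "GRVI", "NPCI",
]
MS_FEATURE_NAMES = BAND_NAMES + VI_NAMES  # 5 + 23 = 28

__all__ = [
    "BAND_NAMES", "VI_NAMES", "MS_FEATURE_NAMES",
    "mean_reflectance", "veg_indexes", "ms_feature_table",
]


def _div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den != 0)
    return out if out.ndim else float(out)


def mean_reflectance(plot: PlotPixelSet) -> dict[str, float]:
    """Zonal mean reflectance per band."""
    if plot.count < 1:
        raise ValueError(f"plot {plot.plot_id} has no pixels")
    means = plot.ms.mean(axis=0)
    return dict(zip(BAND_NAMES, means.astype(float)))


def veg_indexes(r475, r560, r668, r717, r840) -> dict[str, np.ndarray | float]:
    """The twenty-three vegetation indexes.  Accepts scalars or arrays."""
    r475 = np.asarray(r475, dtype=float)
    r560 = np.asarray(r560, dtype=float)
    r668 = np.asarray(r668, dtype=float)
    r717 = np.asarray(r717, dtype=float)
    r840 = np.asarray(r840, dtype=float)

    fd_num = r840 + r717 - r668
    inv475 = _div(1.0, r475)
    inv560 = _div(1.0, r560)
    inv717 = _div(1.0, r717)

    return {
        "FD_VI1": _div(fd_num, r840 + r717 + r668),
        "FD_VI2": _div(fd_num, r840 + r717 + r668 - r475),
        "FD_VI3": _div(fd_num, r840 + r717 + 6.0 * r668 - 7.5 * r475 + 25.0),
        "FD_VI4": _div(
            r840 + r717 + r560 - r668,
            r840 + r717 + r668 + r560 - r475 + 7.0,
        ),
        "NDVI": _div(r840 - r668, r840 + r668),
        "SR": _div(r840, r668),
        "EVI": _div(2.5 * (r840 - r668), r840 + 6.0 * r668 - 7.5 * r475 + 1.0),
        "ARVI": _div(
            r840 - (2.0 * r668 - r475), r840 + (2.0 * r668 - r475)
        ),
        "RENDVI": _div(r840 - r717, r840 + r717),
        "mSR": _div(r840 - r475, r717 + r475),
        "mNDVI": _div(r840 - r717, r840 + r717 - 2.0 * r475),
        "RERVI": _div(r840, r717),
        "PRI": _div(r560 - r668, r560 + r668),
        "SIPI": _div(r840 - r475, r840 + r668),
        "RG": _div(r668, r560),
        "PSRI": _div(r717 - r475, r840),
        "CRI1": inv475 - inv560,
        "CRI2": inv475 - inv717,
        "ARI1": inv560 - inv717,
        "ARI2": (inv560 - inv717) * r840,
        "GNDVI": _div(r840 - r560, r840 + r560),
        "GRVI": _div(r840, r560),
        "NPCI": _div(r668 - r475, r668 + r475),
    }


def ms_feature_table(
    plots: Mapping[int, PlotPixelSet] | Iterable[PlotPixelSet],
    aggregate: str = "mean_first",
) -> pd.DataFrame:
    """One row per plot with the 28 multispectral features.

    ``aggregate`` follows the same convention as the RGB table: indexes on
    zonal mean reflectance (default) or per pixel then averaged.
    """
    if aggregate not in ("mean_first", "per_pixel"):
        raise ValueError("aggregate must be 'mean_first' or 'per_pixel'")
    items = plots.values() if isinstance(plots, Mapping) else plots

    rows = []
    for plot in items:
        row: dict[str, float] = {"plot_id": plot.plot_id}
        bands = mean_reflectance(plot)
        row.update(bands)
        if aggregate == "mean_first":
            vis = veg_indexes(*(bands[b] for b in BAND_NAMES))
        else:
            per_px = veg_indexes(*(plot.ms[:, i] for i in range(5)))
            with np.errstate(invalid="ignore"):
                vis = {
                    k: float(np.nanmean(v)) if not np.isnan(v).all() else float("nan")
                    for k, v in per_px.items()
                }
        row.update(vis)
        rows.append(row)

    table = pd.DataFrame(rows)
    return table[["plot_id"] + MS_FEATURE_NAMES]
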