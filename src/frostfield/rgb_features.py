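"""RGB features per plot: channel means, 15 color indexes, 24 GLCM textures.

Color indexes (CIs) are scalar combinations of the R, G, B digital numbers
designed to enhance vegetation color contrast (ExG, VARI, NGRDI, ...).  By
default they are evaluated on the plot's zonal mean DN; a per-pixel-then-mean
alternative is available through ``aggregate="per_pixel"``.

Texture features come from gray-level co-occurrence matrices (GLCM) computed
per channel over each plot's masked footprint: Mean, Variance, Homogeneity,
Contrast, Dissimilarity, Entropy, Second Moment, and Correlation, yielding
24 features named R_M .. B_Cor.  GLCM parameters (unspecified by most field
protocols) default to 32 linearly quantized gray levels over [0, 255], the
four distance-1 directions, symmetric counting, and feature averaging over
directions.

Zero denominators yield NaN (flagged missing, excluded pairwise downstream),
never an exception.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .imaging import PlotPixelSet

CI_NAMES = [
    "BNI", "GNI", "RNI", "ExG", "VARI", "ExR", "ExB", "ExGR",
    "NGRDI", "MGRVI", "WI", "IKAW", "GLA", "RGBVI", "VEG",
]
TEXTURE_STATS = ["M", "V", "H", "Con", "D", "E", "SM", "Cor"]
TEXTURE_NAMES = [f"{c}_{s}" for c in ("R", "G", "B") for s in TEXTURE_STATS]
DN_NAMES = ["R", "G", "B"]
RGB_FEATURE_NAMES = DN_NAMES + CI_NAMES + TEXTURE_NAMES  # 3 + 15 + 24 = 42

#: distance-1 displacements at 0, 45, 90 and 135 degrees
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

__all__ = [
    "CI_NAMES", "TEXTURE_STATS", "TEXTURE_NAMES", "DN_NAMES",
    "RGB_FEATURE_NAMES", "DEFAULT_OFFSETS",
    "mean_dn", "color_indexes", "quantize", "glcm", "texture_features",
    "plot_texture_features", "rgb_feature_table",
]


def _div(num, den):
    """Elementwise division with NaN (missing flag) on zero denominators."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=den != 0)
    return out if out.ndim else float(out)


def mean_dn(plot: PlotPixelSet) -> dict[str, float]:
    """Zonal mean digital number per channel."""
    if plot.count < 1:
        raise ValueError(f"plot {plot.plot_id} has no pixels")
    means = plot.rgb.mean(axis=0)
    return dict(zip(DN_NAMES, means.astype(float)))


def color_indexes(R, G, B) -> dict[str, np.ndarray | float]:
    """The fifteen vegetation-related color indexes from R, G, B digital
    numbers.  Accepts scalars or equally-shaped arrays."""
    R = np.asarray(R, dtype=float)
    G = np.asarray(G, dtype=float)
    B = np.asarray(B, dtype=float)
    a = 0.667
    exg = 2.0 * G - B - R
    exr = 1.4 * R - G
    exb = 1.4 * B - G
    with np.errstate(divide="ignore", invalid="ignore"):
        veg_den = np.power(R, a) * np.power(B, 1.0 - a)
    out = {
        "BNI": _div(B, B + G + R),
        "GNI": _div(G, B + G + R),
        "RNI": _div(R, B + G + R),
        "ExG": exg if exg.ndim else float(exg),
        "VARI": _div(G - R, G + R - B),
        "ExR": exr if exr.ndim else float(exr),
        "ExB": exb if exb.ndim else float(exb),
        "ExGR": (exg - exr) if exg.ndim else float(exg - exr),
        "NGRDI": _div(G - R, G + R),
        "MGRVI": _div(G**2 - R**2, G**2 + R**2),
        "WI": _div(G - B, R - G),
        "IKAW": _div(R - B, R + B),
        "GLA": _div(2.0 * G - R - B, 2.0 * G + R + B),
        "RGBVI": _div(G**2 - B * R, G**2 + B * R),
        "VEG": _div(G, veg_den),
    }
    return out


def quantize(
    values: np.ndarray, n_levels: int = 32, value_range: tuple[float, float] = (0.0, 255.0)
) -> np.ndarray:
    """Linear quantization to gray levels 0 .. n_levels-1 with fixed breakpoints."""
    lo, hi = value_range
    if hi <= lo:
        raise ValueError("value_range must be increasing")
    q = np.floor((np.asarray(values, float) - lo) / (hi - lo + 1.0) * n_levels)
    return np.clip(q, 0, n_levels - 1).astype(np.intp)


def _glcm_counts(
    levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int],
    n_levels: int, symmetric: bool,
) -> np.ndarray:
    dr, dc = offset
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((n_levels, n_levels), dtype=np.int64)
    src = levels[r0:r1, c0:c1]
    dst = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    i = src[valid]
    j = dst[valid]
    counts = np.bincount(i * n_levels + j, minlength=n_levels * n_levels)
    counts = counts.reshape(n_levels, n_levels)
    if symmetric:
        counts = counts + counts.T
    return counts


def glcm(
    grid: np.ndarray,
    mask: np.ndarray | None = None,
    n_levels: int = 32,
    offsets: Iterable[tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    value_range: tuple[float, float] = (0.0, 255.0),
    average: bool = True,
):
    """Normalized gray-level co-occurrence matrix over masked pixel pairs.

    Only pairs with both pixels inside ``mask`` are counted; each offset's
    count matrix is normalized to probabilities.  With ``average=True`` the
    per-offset matrices are averaged into one; otherwise a list (one matrix
    per offset, ``None`` where the offset has no valid pair) is returned.
    Returns ``None`` (texture undefined) if no offset has any valid pair.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    levels = quantize(grid, n_levels=n_levels, value_range=value_range)

    mats: list[np.ndarray | None] = []
    for off in offsets:
        counts = _glcm_counts(levels, np.asarray(mask, bool), off, n_levels, symmetric)
        total = counts.sum()
        mats.append(counts / total if total > 0 else None)
    if not average:
        return mats
    valid = [p for p in mats if p is not None]
    if not valid:
        return None
    return np.mean(valid, axis=0)


def texture_features(p: np.ndarray, log_base: float | None = None) -> dict[str, float]:
    """The eight GLCM texture statistics of a probability matrix ``p``.

    Entropy uses the natural log unless ``log_base`` is given; ``0 log 0`` is
    taken as 0.  Correlation uses the standard product-moment numerator
    ``sum_ij i*j*p(i,j) - mu_x*mu_y`` and is NaN when either marginal is
    degenerate.
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    if p.shape != (n, n) or (p < 0).any():
        raise ValueError("p must be a square non-negative matrix")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("p must sum to 1")

    idx = np.arange(n, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ii = idx[:, None]
    jj = idx[None, :]

    mean = float((idx * px).sum())
    variance = float(((idx - mean) ** 2 * px).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    dissimilarity = float((p * np.abs(ii - jj)).sum())
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    if log_base is not None:
        entropy /= math.log(log_base)
    second_moment = float((p**2).sum())

    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = math.sqrt(float(((idx - mu_x) ** 2 * px).sum()))
    sd_y = math.sqrt(float(((idx - mu_y) ** 2 * py).sum()))
    if sd_x * sd_y > 0:
        correlation = (float((ii * jj * p).sum()) - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = float("nan")

    return {
        "M": mean, "V": variance, "H": homogeneity, "Con": contrast,
        "D": dissimilarity, "E": entropy, "SM": second_moment,
        "Cor": correlation,
    }


def plot_texture_features(
    grid: np.ndarray,
    mask: np.ndarray | None = None,
    n_levels: int = 32,
    offsets: Iterable[tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    value_range: tuple[float, float] = (0.0, 255.0),
    log_base: float | None = None,
) -> dict[str, float]:
    """Texture statistics of one channel patch, averaged over directions.

    Features are computed per offset and then averaged (directions with no
    valid pair are skipped; all-NaN gives NaN, the texture-undefined flag).
    """
    mats = glcm(
        grid, mask=mask, n_levels=n_levels, offsets=offsets,
        symmetric=symmetric, value_range=value_range, average=False,
    )
    per_offset = [texture_features(p, log_base=log_base) for p in mats if p is not None]
    if not per_offset:
        return {s: float("nan") for s in TEXTURE_STATS}
    out = {}
    for s in TEXTURE_STATS:
        vals = np.array([f[s] for f in per_offset])
        with np.errstate(invalid="ignore"):
            out[s] = float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")
    return out


def rgb_feature_table(
    plots: Mapping[int, PlotPixelSet] | Iterable[PlotPixelSet],
    n_levels: int = 32,
    offsets: Iterable[tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    log_base: float | None = None,
    aggregate: str = "mean_first",
) -> pd.DataFrame:
    """One row per plot with the 42 RGB features (3 DN + 15 CI + 24 texture).

    ``aggregate="mean_first"`` evaluates CIs on zonal mean DN (default);
    ``"per_pixel"`` evaluates them per pixel and averages the defined values.
    """
    if aggregate not in ("mean_first", "per_pixel"):
        raise ValueError("aggregate must be 'mean_first' or 'per_pixel'")
    items = plots.values() if isinstance(plots, Mapping) else plots

    rows = []
    for plot in items:
        row: dict[str, float] = {"plot_id": plot.plot_id}
        row.update(mean_dn(plot))
        if aggregate == "mean_first":
            cis = color_indexes(row["R"], row["G"], row["B"])
        else:
            per_px = color_indexes(plot.rgb[:, 0], plot.rgb[:, 1], plot.rgb[:, 2])
            with np.errstate(invalid="ignore"):
                cis = {
                    k: float(np.nanmean(v)) if not np.isnan(v).all() else float("nan")
                    for k, v in per_px.items()
                }
        row.update(cis)
        for c, name in zip(range(3), ("R", "G", "B")):
            feats = plot_texture_features(
                plot.rgb_patch[c], mask=plot.mask_patch, n_levels=n_levels,
                offsets=offsets, symmetric=symmetric, log_base=log_base,
            )
            row.update({f"{name}_{s}": v for s, v in feats.items()})
        rows.append(row)

    table = pd.DataFrame(rows)
    return table[["plot_id"] + RGB_FEATURE_NAMES]
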