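"""Radiometric calibration, NDVI segmentation and per-plot zonal extraction.

The survey workflow: digital numbers are converted to reflectance against a
gray reference panel of known reflectance; vegetation is separated from soil
by an NDVI > 0.5 decision rule on the *healthy* (pre-frost) scene, cleaned
with a majority filter; the resulting vegetation footprint is intersected
with the plot-label map and applied to the *post-frost* scene to pull out
each plot's pixel population for feature extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
import tifffile

from .synthetic_field import BAND_CENTERS_NM, SceneRasterSet

# band order of the multispectral raster
BAND_INDEX = {c: i for i, c in enumerate(BAND_CENTERS_NM)}
RED_BAND = BAND_INDEX[668]
NIR_BAND = BAND_INDEX[840]

__all__ = [
    "CalibrationPanel",
    "VegetationMask",
    "PlotPixelSet",
    "radiometric_calibrate",
    "ndvi",
    "ndvi_mask",
    "majority_filter",
    "zonal_extract",
    "read_raster",
    "write_raster",
    "read_scene",
]


@dataclass(frozen=True)
class CalibrationPanel:
    """Reference panel: known reflectance and its observed DN per band."""

    panel_dn: tuple[float, ...]
    panel_reflectance: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.panel_reflectance <= 1.0:
            raise ValueError("panel_reflectance must lie in (0, 1]")
        if any(d <= 0 for d in self.panel_dn):
            raise ValueError("panel DN must be positive in every band")


@dataclass
class VegetationMask:
    """Boolean vegetation raster plus the NDVI threshold that produced it."""

    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PlotPixelSet:
    """Masked pixel population of one plot.

    ``rgb`` / ``ms`` are flat (n, channels) vectors of the retained pixels;
    the ``*_patch`` arrays keep the bounding-box geometry (channels, h, w)
    with ``mask_patch`` marking the in-plot pixels, which texture features
    need.
    """

    plot_id: int
    rgb: np.ndarray
    ms: np.ndarray
    rgb_patch: np.ndarray = field(repr=False, default=None)
    ms_patch: np.ndarray = field(repr=False, default=None)
    mask_patch: np.ndarray = field(repr=False, default=None)

    @property
    def count(self) -> int:
        return self.rgb.shape[0]


def radiometric_calibrate(
    raw_dn: np.ndarray, panel: CalibrationPanel
) -> np.ndarray:
    """DN -> reflectance with the per-band panel gain, clipped to [0, 1].

    ``reflectance = dn * panel_reflectance / panel_dn`` per band.
    """
    raw = np.asarray(raw_dn, dtype=float)
    if raw.ndim != 3 or raw.shape[0] != len(panel.panel_dn):
        raise ValueError(
            f"raster has {raw.shape[0] if raw.ndim == 3 else '?'} bands, "
            f"panel has {len(panel.panel_dn)}"
        )
    gain = panel.panel_reflectance / np.asarray(panel.panel_dn, dtype=float)
    return np.clip(raw * gain[:, None, None], 0.0, 1.0)


def ndvi(ms: np.ndarray, red_band: int = RED_BAND, nir_band: int = NIR_BAND) -> np.ndarray:
    """(NIR - red) / (NIR + red); 0 where the denominator vanishes."""
    ms = np.asarray(ms, dtype=float)
    if ms.ndim != 3 or ms.shape[0] <= max(red_band, nir_band):
        raise ValueError("multispectral raster misses the red or NIR band")
    red = ms[red_band]
    nir = ms[nir_band]
    den = nir + red
    out = np.zeros_like(den)
    np.divide(nir - red, den, out=out, where=den != 0)
    return out


def ndvi_mask(ms: np.ndarray, threshold: float = 0.5) -> VegetationMask:
    """Vegetation where NDVI exceeds the threshold (zero-denominator pixels
    are background)."""
    index = ndvi(ms)
    den = np.asarray(ms, dtype=float)[NIR_BAND] + np.asarray(ms, dtype=float)[RED_BAND]
    mask = (index > threshold) & (den != 0)
    return VegetationMask(mask=mask, threshold=threshold)


def majority_filter(
    mask: VegetationMask | np.ndarray,
    window: int = 3,
    center_weight: int = 2,
) -> VegetationMask:
    """Neighborhood majority vote removing small misclassified plaques.

    Each pixel takes the weighted majority class of its ``window x window``
    neighborhood (outside the image counts as background); ties keep the
    original value.  The center pixel carries ``center_weight`` votes — with
    the default of 2, isolated pixels are still removed while right-angle
    corners of solid rectangular footprints are preserved, so blocks at least
    as large as the window are exact fixed points.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if center_weight < 1:
        raise ValueError("center_weight must be >= 1")
    src = mask if isinstance(mask, VegetationMask) else VegetationMask(mask, float("nan"))
    m = src.mask.astype(np.int64)

    kernel = np.ones((window, window), dtype=np.int64)
    true_votes = ndimage.convolve(m, kernel, mode="constant", cval=0)
    total_votes = ndimage.convolve(np.ones_like(m), kernel, mode="constant", cval=0)
    true_votes += (center_weight - 1) * m
    total_votes = total_votes + (center_weight - 1)

    out = src.mask.copy()
    out[2 * true_votes > total_votes] = True
    out[2 * true_votes < total_votes] = False
    return VegetationMask(mask=out, threshold=src.threshold)


def zonal_extract(
    scene: SceneRasterSet,
    mask: VegetationMask | np.ndarray,
) -> tuple[dict[int, PlotPixelSet], list[int]]:
    """Per-plot pixel populations where ``label == id`` and the mask is true.

    Returns ``(plots, dropped)`` where ``dropped`` lists plot ids whose
    footprint was entirely masked out (reported, not silently lost).
    """
    m = mask.mask if isinstance(mask, VegetationMask) else np.asarray(mask, bool)
    if m.shape != scene.labels.shape:
        raise ValueError(
            f"mask shape {m.shape} does not match labels {scene.labels.shape}"
        )

    plots: dict[int, PlotPixelSet] = {}
    dropped: list[int] = []
    objects = ndimage.find_objects(scene.labels)
    for plot_id, sl in enumerate(objects, start=1):
        if sl is None:
            dropped.append(plot_id)
            continue
        in_plot = (scene.labels[sl] == plot_id) & m[sl]
        if not in_plot.any():
            dropped.append(plot_id)
            continue
        rgb_patch = scene.rgb[(slice(None),) + sl]
        ms_patch = scene.ms[(slice(None),) + sl]
        plots[plot_id] = PlotPixelSet(
            plot_id=plot_id,
            rgb=rgb_patch[:, in_plot].T.copy(),
            ms=ms_patch[:, in_plot].T.copy(),
            rgb_patch=rgb_patch.copy(),
            ms_patch=ms_patch.copy(),
            mask_patch=in_plot,
        )
    return plots, dropped


# ---------------------------------------------------------------------------
# raster / fixture readers (counterparts of synthetic_field.write_fixture)

def read_raster(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_raster(path: str | Path, array: np.ndarray) -> None:
    tifffile.imwrite(path, array)


def read_scene(fixture_dir: str | Path) -> SceneRasterSet:
    """Load a scene written by :func:`frostfield.synthetic_field.write_fixture`."""
    d = Path(fixture_dir)
    band_centers = BAND_CENTERS_NM
    manifest = d / "manifest.json"
    if manifest.exists():
        meta = json.loads(manifest.read_text())
        band_centers = tuple(meta.get("band_centers_nm", band_centers))
    return SceneRasterSet(
        rgb=read_raster(d / "rgb.tif"),
        ms=read_raster(d / "ms.tif"),
        labels=read_raster(d / "labels.tif"),
        band_centers=band_centers,
    )
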