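"""Synthetic frost-trial field: known damage grades, rendered scene rasters.

The real survey data of a lettuce cultivar trial (a grid of small breeding
plots, two cultivar color classes, per-plant ordinal damage grades) are not
public, so every downstream stage is exercised on a generated stand-in with
known ground truth.  The generator emulates the physical mechanism of frost
damage on canopy spectra: chlorophyll breakdown raises blue- and red-band
reflectance, cell-structure collapse lowers near-infrared reflectance, and the
green band responds with opposite sign in green vs anthocyanin-rich red
cultivars.  The per-plot response is linear in the normalized damage (the FDI)
with additive Gaussian pixel noise and an independent per-plot (cultivar)
baseline offset.

Rasters: an RGB digital-number raster (values 0..255, kept real-valued so the
response stays exactly linear), a 5-band reflectance raster (band centers
475/560/668/717/840 nm) and an integer plot-label map (0 = soil background).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frost_index import LEVEL_PREFIX, compute_fdi

BAND_CENTERS_NM = (475, 560, 668, 717, 840)
GREEN = "green"
RED = "red"

__all__ = [
    "BAND_CENTERS_NM",
    "GREEN",
    "RED",
    "FieldDesign",
    "CultivarResponse",
    "SpectralResponseModel",
    "SceneRasterSet",
    "sample_damage_grades",
    "render_scene",
    "write_fixture",
]


@dataclass(frozen=True)
class FieldDesign:
    """Layout and scale of the synthetic trial.

    Defaults follow the surveyed trial: 209 plots (160 green, 49 red
    cultivars) of ~24 plants each, graded on an ordinal 0..5 scale.
    """

    n_plots: int = 209
    n_green: int = 160
    n_red: int = 49
    plants_per_plot: int = 24
    plot_shape_px: tuple[int, int] = (10, 24)
    max_damage_level: int = 5
    seed: int = 0
    gap_px: int = 4

    def __post_init__(self) -> None:
        if self.n_green + self.n_red != self.n_plots:
            raise ValueError("n_green + n_red must equal n_plots")
        if min(self.n_plots, self.n_green, self.n_red) <= 0:
            raise ValueError("plot counts must be positive")
        if self.plants_per_plot < 1:
            raise ValueError("plants_per_plot must be >= 1")
        if self.max_damage_level < 1:
            raise ValueError("max_damage_level must be >= 1")
        if min(self.plot_shape_px) < 1 or self.gap_px < 1:
            raise ValueError("plot shape and gap must be positive")


@dataclass(frozen=True)
class CultivarResponse:
    """Linear spectral response of one cultivar color class.

    ``ms_*`` are reflectances per band (475/560/668/717/840 nm), ``dn_*`` are
    RGB digital numbers per channel (R, G, B).  Slopes are the signed change
    per unit normalized damage (FDI in [0, 1]).
    """

    ms_baseline: tuple[float, ...]
    ms_slope: tuple[float, ...]
    dn_baseline: tuple[float, ...]
    dn_slope: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ms_baseline) != 5 or len(self.ms_slope) != 5:
            raise ValueError("multispectral parameters need 5 bands")
        if len(self.dn_baseline) != 3 or len(self.dn_slope) != 3:
            raise ValueError("RGB parameters need 3 channels")
        if not all(0.0 <= b <= 1.0 for b in self.ms_baseline):
            raise ValueError("baseline reflectance must lie in [0, 1]")
        # frost mechanism: blue/red reflectance rises, NIR falls with damage
        if self.ms_slope[0] <= 0 or self.ms_slope[2] <= 0:
            raise ValueError("blue (475) and red (668) slopes must be > 0")
        if self.ms_slope[4] >= 0:
            raise ValueError("NIR (840) slope must be < 0")


@dataclass(frozen=True)
class SpectralResponseModel:
    """Scene-level response: one parameter set per cultivar color, plus soil,
    pixel noise, and between-plot (cultivar) baseline jitter."""

    green: CultivarResponse
    red: CultivarResponse
    soil_reflectance: tuple[float, ...] = (0.10, 0.14, 0.18, 0.22, 0.26)
    soil_dn: tuple[float, ...] = (120.0, 100.0, 85.0)
    noise_sd_reflectance: float = 0.01
    noise_sd_dn: float = 3.0
    plot_sd_reflectance: float = 0.02
    plot_sd_dn: float = 8.0

    def __post_init__(self) -> None:
        if self.green.ms_baseline[1] == self.red.ms_baseline[1]:
            raise ValueError("green-band baselines must differ between colors")
        if min(
            self.noise_sd_reflectance,
            self.noise_sd_dn,
            self.plot_sd_reflectance,
            self.plot_sd_dn,
        ) < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def for_color(self, color: str) -> CultivarResponse:
        if color == GREEN:
            return self.green
        if color == RED:
            return self.red
        raise ValueError(f"unknown cultivar color {color!r}")

    @classmethod
    def default(cls) -> "SpectralResponseModel":
        """Study-condition defaults.

        Green cultivars: bright green leaf (high 560/840 reflectance, G
        channel dominant); damage turns leaves yellow-brown (R/B up, G
        slightly down).  Red cultivars: anthocyanin absorbs green light, so
        the green band starts low and *rises* when anthocyanin breaks down.
        """
        green = CultivarResponse(
            ms_baseline=(0.04, 0.12, 0.05, 0.25, 0.50),
            ms_slope=(0.06, -0.02, 0.08, -0.05, -0.20),
            dn_baseline=(60.0, 110.0, 50.0),
            dn_slope=(70.0, -25.0, 35.0),
        )
        red = CultivarResponse(
            ms_baseline=(0.05, 0.07, 0.06, 0.22, 0.45),
            ms_slope=(0.07, 0.09, 0.08, -0.05, -0.18),
            dn_baseline=(85.0, 60.0, 55.0),
            dn_slope=(60.0, 50.0, 35.0),
        )
        return cls(green=green, red=red)

    @classmethod
    def noiseless(cls) -> "SpectralResponseModel":
        """Defaults with every random component switched off."""
        return dataclasses.replace(
            cls.default(),
            noise_sd_reflectance=0.0,
            noise_sd_dn=0.0,
            plot_sd_reflectance=0.0,
            plot_sd_dn=0.0,
        )


@dataclass
class SceneRasterSet:
    """Co-registered rasters: RGB DN (3,H,W), reflectance (5,H,W), labels (H,W)."""

    rgb: np.ndarray
    ms: np.ndarray
    labels: np.ndarray
    band_centers: tuple[int, ...] = BAND_CENTERS_NM

    def __post_init__(self) -> None:
        if self.rgb.shape[0] != 3 or self.ms.shape[0] != 5:
            raise ValueError("rgb must have 3 bands and ms 5 bands")
        if not (self.rgb.shape[1:] == self.ms.shape[1:] == self.labels.shape):
            raise ValueError("rasters are not co-registered (shape mismatch)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def sample_damage_grades(
    design: FieldDesign,
    severity_spread: float = 1.0,
    concentration: float = 8.0,
) -> pd.DataFrame:
    """Draw per-plant damage grades for every plot.

    Each plot gets a latent severity ``s ~ U(0, severity_spread)``; plant
    grades are beta-binomial around it (``p ~ Beta`` with mean ``s`` and the
    given concentration, grade ``~ Binomial(MAX_DL, p)``), so plot-mean
    severity spans the full range while plants within a plot disagree the way
    field plants do.  ``severity_spread=0`` is the all-healthy field.
    """
    if not 0.0 <= severity_spread <= 1.0:
        raise ValueError("severity_spread must lie in [0, 1]")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")

    rng = np.random.default_rng(design.seed)
    colors = np.array([GREEN] * design.n_green + [RED] * design.n_red)
    rng.shuffle(colors)
    severities = rng.uniform(0.0, severity_spread, design.n_plots)

    max_dl = design.max_damage_level
    rows = np.zeros((design.n_plots, max_dl + 1), dtype=int)
    for k, s in enumerate(severities):
        if s <= 0.0:
            rows[k, 0] = design.plants_per_plot
            continue
        p = rng.beta(s * concentration, (1.0 - s) * concentration,
                     design.plants_per_plot)
        grades = rng.binomial(max_dl, p)
        rows[k] = np.bincount(grades, minlength=max_dl + 1)

    table = pd.DataFrame(
        rows, columns=[f"{LEVEL_PREFIX}{i}" for i in range(max_dl + 1)]
    )
    table.insert(0, "cultivar_color", colors)
    table.insert(0, "plot_id", np.arange(1, design.n_plots + 1))
    return table


def _grid_layout(design: FieldDesign) -> tuple[int, int]:
    ncols = int(math.ceil(math.sqrt(design.n_plots)))
    nrows = int(math.ceil(design.n_plots / ncols))
    return nrows, ncols


def render_scene(
    design: FieldDesign,
    grades: pd.DataFrame,
    response: SpectralResponseModel | None = None,
    rng: np.random.Generator | None = None,
) -> SceneRasterSet:
    """Render co-registered RGB / multispectral / label rasters.

    Plots are solid rectangles on a regular grid separated by soil gaps; each
    plot's pixels follow ``baseline + slope * FDI`` for its cultivar color
    (plus plot jitter and pixel noise), soil pixels carry the soil values.
    """
    if response is None:
        response = SpectralResponseModel.default()
    if rng is None:
        # independent of the grade-sampling stream but still seed-determined
        rng = np.random.default_rng(design.seed + 1_000_003)

    missing = set(range(1, design.n_plots + 1)) - set(grades["plot_id"])
    if missing:
        raise ValueError(f"grade table misses plots {sorted(missing)}")

    fdi = compute_fdi(grades, max_damage_level=design.max_damage_level)
    damage = dict(zip(fdi["plot_id"], fdi["fdi"]))
    color = dict(zip(grades["plot_id"], grades["cultivar_color"]))

    ph, pw = design.plot_shape_px
    gap = design.gap_px
    nrows, ncols = _grid_layout(design)
    height = nrows * ph + (nrows + 1) * gap
    width = ncols * pw + (ncols + 1) * gap

    ms = np.empty((5, height, width), dtype=float)
    rgb = np.empty((3, height, width), dtype=float)
    ms[:] = np.asarray(response.soil_reflectance)[:, None, None]
    rgb[:] = np.asarray(response.soil_dn)[:, None, None]
    labels = np.zeros((height, width), dtype=np.int32)

    if response.noise_sd_reflectance > 0:
        ms += rng.normal(0.0, response.noise_sd_reflectance, ms.shape)
    if response.noise_sd_dn > 0:
        rgb += rng.normal(0.0, response.noise_sd_dn, rgb.shape)

    for plot_id in range(1, design.n_plots + 1):
        k = plot_id - 1
        r0 = gap + (k // ncols) * (ph + gap)
        c0 = gap + (k % ncols) * (pw + gap)
        cresp = response.for_color(color[plot_id])
        d = damage[plot_id]

        mean_ms = np.asarray(cresp.ms_baseline) + np.asarray(cresp.ms_slope) * d
        mean_dn = np.asarray(cresp.dn_baseline) + np.asarray(cresp.dn_slope) * d
        if response.plot_sd_reflectance > 0:
            mean_ms = mean_ms + rng.normal(0.0, response.plot_sd_reflectance, 5)
        if response.plot_sd_dn > 0:
            mean_dn = mean_dn + rng.normal(0.0, response.plot_sd_dn, 3)

        px_ms = np.broadcast_to(mean_ms[:, None, None], (5, ph, pw)).copy()
        px_dn = np.broadcast_to(mean_dn[:, None, None], (3, ph, pw)).copy()
        if response.noise_sd_reflectance > 0:
            px_ms += rng.normal(0.0, response.noise_sd_reflectance, px_ms.shape)
        if response.noise_sd_dn > 0:
            px_dn += rng.normal(0.0, response.noise_sd_dn, px_dn.shape)

        ms[:, r0 : r0 + ph, c0 : c0 + pw] = px_ms
        rgb[:, r0 : r0 + ph, c0 : c0 + pw] = px_dn
        labels[r0 : r0 + ph, c0 : c0 + pw] = plot_id

    np.clip(ms, 0.0, 1.0, out=ms)
    np.clip(rgb, 0.0, 255.0, out=rgb)
    return SceneRasterSet(rgb=rgb, ms=ms, labels=labels)


def write_fixture(
    scene: SceneRasterSet,
    grades: pd.DataFrame,
    out_dir: str | Path,
    design: FieldDesign | None = None,
    extra: dict | None = None,
) -> dict:
    """Write a scene + grade table + JSON manifest to ``out_dir``.

    Rasters round-trip losslessly (float64 / int32 TIFF).  Returns the
    manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        tifffile.imwrite(out / "rgb.tif", scene.rgb, photometric="minisblack")
        tifffile.imwrite(out / "ms.tif", scene.ms, photometric="minisblack")
        tifffile.imwrite(out / "labels.tif", scene.labels, photometric="minisblack")
        grades.to_csv(out / "grades.csv", index=False)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing fixture under {out}: {exc}") from exc

    manifest = {
        "files": {
            "rgb": "rgb.tif",
            "ms": "ms.tif",
            "labels": "labels.tif",
            "grades": "grades.csv",
        },
        "band_centers_nm": list(scene.band_centers),
        "n_plots": int(grades.shape[0]),
    }
    if design is not None:
        manifest["seed"] = design.seed
        manifest["design"] = dataclasses.asdict(design)
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
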