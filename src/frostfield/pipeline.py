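"""End-to-end orchestration: fixture -> mask -> features -> selection -> models.

The survey design uses two co-registered scenes: the *mask scene* (acquired
while the canopy was healthy, so vegetation separates cleanly from soil) from
which the NDVI > 0.5 footprint is derived, and the *feature scene* (acquired
after the frost events) from which all features are extracted under that
footprint.  ``run_all`` executes the whole chain from a fixture directory and
writes feature tables, the selection report, model reports, figures and a run
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import frost_index, imaging, modeling, ms_features, rgb_features, selection
from .synthetic_field import (
    FieldDesign,
    SceneRasterSet,
    SpectralResponseModel,
    render_scene,
    sample_damage_grades,
    write_fixture,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "simulate_fixture", "build_feature_table", "run_all"]


@dataclass
class RunConfig:
    """Paths and knobs of one pipeline run."""

    fixture_dir: str
    out_dir: str
    mask_scene: str = "mask_scene"      # subdir with the healthy-date scene
    feature_scene: str = "feature_scene"
    grades_csv: str = "grades.csv"
    ndvi_threshold: float = 0.5
    majority_window: int = 3
    majority_center_weight: int = 2
    glcm_levels: int = 32
    alpha: float = 0.01
    split_ratio: float = 0.7
    n_strata: int = 5
    split_seed: int = 0
    nn_seed: int = 0
    sources: tuple[str, ...] = modeling.SOURCES
    algorithms: tuple[str, ...] = modeling.ALGORITHMS
    figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sources", "algorithms"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def simulate_fixture(
    out_dir: str | Path,
    seed: int = 0,
    design: FieldDesign | None = None,
    response: SpectralResponseModel | None = None,
    severity_spread: float = 1.0,
) -> dict:
    """Generate a two-date fixture: healthy mask scene + damaged feature scene.

    Both scenes share the design and spectral response; the mask scene is
    rendered with an all-healthy grade table (the pre-frost survey), the
    feature scene with the sampled damage grades.
    """
    if design is None:
        design = FieldDesign(seed=seed)
    elif design.seed != seed:
        design = dataclasses.replace(design, seed=seed)
    if response is None:
        response = SpectralResponseModel.default()

    grades = sample_damage_grades(design, severity_spread=severity_spread)
    healthy = grades.copy()
    level_cols = frost_index.level_columns(grades)
    healthy[level_cols] = 0
    healthy[level_cols[0]] = design.plants_per_plot

    rng = np.random.default_rng(seed + 7_919)
    mask_scene = render_scene(design, healthy, response, rng=rng)
    feature_scene = render_scene(design, grades, response, rng=rng)

    out = Path(out_dir)
    write_fixture(mask_scene, healthy, out / "mask_scene", design=design)
    write_fixture(feature_scene, grades, out / "feature_scene", design=design)
    grades.to_csv(out / "grades.csv", index=False)
    manifest = {
        "seed": seed,
        "severity_spread": severity_spread,
        "design": dataclasses.asdict(design),
        "scenes": {"mask_scene": "mask_scene", "feature_scene": "feature_scene"},
        "grades": "grades.csv",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def build_feature_table(
    mask_scene: SceneRasterSet,
    feature_scene: SceneRasterSet,
    grades: pd.DataFrame,
    ndvi_threshold: float = 0.5,
    majority_window: int = 3,
    majority_center_weight: int = 2,
    glcm_levels: int = 32,
    max_damage_level: int | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Segment, extract and assemble the per-plot feature table.

    Returns ``(table, dropped)``: one row per retained plot with plot_id,
    cultivar_color, fdi and the 70 features; ``dropped`` lists plots whose
    footprint vanished under the mask.
    """
    mask = imaging.ndvi_mask(mask_scene.ms, threshold=ndvi_threshold)
    mask = imaging.majority_filter(
        mask, window=majority_window, center_weight=majority_center_weight
    )
    plots, dropped = imaging.zonal_extract(feature_scene, mask)

    rgb_table = rgb_features.rgb_feature_table(plots, n_levels=glcm_levels)
    ms_table = ms_features.ms_feature_table(plots)
    fdi = frost_index.compute_fdi(grades, max_damage_level=max_damage_level)

    table = (
        grades[["plot_id", "cultivar_color"]]
        .merge(fdi, on="plot_id")
        .merge(rgb_table, on="plot_id")
        .merge(ms_table, on="plot_id")
    )
    return table, dropped


def _load_grades(path: Path) -> pd.DataFrame:
    grades = pd.read_csv(path)
    if "plot_id" not in grades.columns:
        raise ValueError(f"{path} lacks a plot_id column")
    return grades


def run_all(config: RunConfig) -> dict:
    """Run every stage and write all reports under ``config.out_dir``."""
    t0 = time.time()
    fixture = Path(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        timings[stage] = round(time.time() - t0 - sum(timings.values()), 3)
        logger.info("stage %s done (%.2fs)", stage, timings[stage])

    try:
        mask_scene = imaging.read_scene(fixture / config.mask_scene)
        feature_scene = imaging.read_scene(fixture / config.feature_scene)
        grades = _load_grades(fixture / config.grades_csv)
        tick("load")

        table, dropped = build_feature_table(
            mask_scene, feature_scene, grades,
            ndvi_threshold=config.ndvi_threshold,
            majority_window=config.majority_window,
            majority_center_weight=config.majority_center_weight,
            glcm_levels=config.glcm_levels,
        )
        table.to_csv(out / "features.csv", index=False)
        pd.DataFrame({"plot_id": dropped}).to_csv(
            out / "dropped_plots.csv", index=False
        )
        tick("features")

        report = selection.select_features(
            table,
            alpha=config.alpha,
            feature_cols=list(modeling.SOURCE_FEATURES["MULTISOURCE"]),
        )
        report.to_csv(out / "selection.csv", index=False)
        tick("selection")

        reports, skipped = modeling.run_cells(
            table, report,
            sources=config.sources, algorithms=config.algorithms,
            ratio=config.split_ratio, n_strata=config.n_strata,
            split_seed=config.split_seed, nn_seed=config.nn_seed,
        )
        records = pd.DataFrame([r.to_record() for r in reports])
        records.to_csv(out / "model_reports.csv", index=False)
        preds = pd.concat(
            [
                r.predictions.assign(
                    group=r.group, source=r.source, algorithm=r.algorithm
                )
                for r in reports
            ],
            ignore_index=True,
        ) if reports else pd.DataFrame()
        preds.to_csv(out / "predictions.csv", index=False)
        (out / "skipped_cells.json").write_text(json.dumps(skipped, indent=2))
        tick("models")

        if config.figures:
            from . import report as report_mod

            report_mod.correlation_heatmap(report, out / "correlation_heatmap.png")
            report_mod.prediction_scatter(reports, out / "scatter")
            tick("figures")
    except Exception as exc:
        stage = "unknown"
        for name in ("figures", "models", "selection", "features", "load"):
            if name not in timings:
                stage = name
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "n_plots": int(table.shape[0]),
        "n_dropped": len(dropped),
        "n_model_cells": len(reports),
        "skipped": skipped,
        "timings_s": timings,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
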