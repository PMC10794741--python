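import numpy as np
import pandas as pd
import pytest

import frostfield as ff
from frostfield import frost_index, pipeline


def healthy_copy(grades: pd.DataFrame, plants_per_plot: int) -> pd.DataFrame:
    """Grade table with every plant at level 0 (the pre-frost survey)."""
    healthy = grades.copy()
    cols = frost_index.level_columns(grades)
    healthy[cols] = 0
    healthy[cols[0]] = plants_per_plot
    return healthy


def make_field(seed=7, noiseless=True, **design_kw):
    """Small field: (design, grades, mask_scene, feature_scene)."""
    kw = dict(
        n_plots=12, n_green=8, n_red=4, plants_per_plot=24,
        plot_shape_px=(6, 8), max_damage_level=5, seed=seed,
    )
    kw.update(design_kw)
    design = ff.FieldDesign(**kw)
    response = (
        ff.SpectralResponseModel.noiseless()
        if noiseless else ff.SpectralResponseModel.default()
    )
    grades = ff.sample_damage_grades(design)
    healthy = healthy_copy(grades, design.plants_per_plot)
    rng = np.random.default_rng(seed + 7_919)
    mask_scene = ff.render_scene(design, healthy, response, rng=rng)
    feature_scene = ff.render_scene(design, grades, response, rng=rng)
    return design, grades, mask_scene, feature_scene


@pytest.fixture(scope="session")
def small_field():
    """Noiseless 12-plot field with damage."""
    return make_field(seed=7, noiseless=True)


@pytest.fixture(scope="session")
def small_plots(small_field):
    """Zonal pixel sets of the noiseless field (healthy-date mask)."""
    from frostfield import imaging

    _, _, mask_scene, feature_scene = small_field
    mask = imaging.majority_filter(imaging.ndvi_mask(mask_scene.ms))
    plots, dropped = imaging.zonal_extract(feature_scene, mask)
    assert not dropped
    return plots


@pytest.fixture(scope="session")
def noisy_table():
    """Feature table of a noisy mid-size field (40 plots) for selection and
    modeling tests."""
    design, grades, mask_scene, feature_scene = make_field(
        seed=3, noiseless=False, n_plots=40, n_green=28, n_red=12
    )
    table, dropped = pipeline.build_feature_table(mask_scene, feature_scene, grades)
    assert not dropped
    return table
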