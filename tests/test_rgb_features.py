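import math

import numpy as np
import pytest

from frostfield.imaging import PlotPixelSet
from frostfield.rgb_features import (
    CI_NAMES,
    DEFAULT_OFFSETS,
    RGB_FEATURE_NAMES,
    TEXTURE_NAMES,
    color_indexes,
    glcm,
    mean_dn,
    plot_texture_features,
    quantize,
    rgb_feature_table,
    texture_features,
)


def pixel_set(rgb_pixels, plot_id=1):
    rgb = np.asarray(rgb_pixels, dtype=float)
    n = rgb.shape[0]
    return PlotPixelSet(
        plot_id=plot_id,
        rgb=rgb,
        ms=np.zeros((n, 5)),
        rgb_patch=rgb.T.reshape(3, n, 1),
        ms_patch=np.zeros((5, n, 1)),
        mask_patch=np.ones((n, 1), bool),
    )


# ---------------------------------------------------------------------------
# oracle: naive double-loop GLCM and texture statistics

def oracle_glcm(levels, mask, offset, n_levels, symmetric):
    counts = np.zeros((n_levels, n_levels))
    h, w = levels.shape
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[levels[r, c], levels[r2, c2]] += 1
                if symmetric:
                    counts[levels[r2, c2], levels[r, c]] += 1
    total = counts.sum()
    return counts / total if total else None


def oracle_textures(p):
    n = p.shape[0]
    mean = var = hom = con = dis = ent = sm = 0.0
    mu_x = mu_y = 0.0
    for i in range(n):
        for j in range(n):
            mu_x += i * p[i, j]
            mu_y += j * p[i, j]
            mean += i * p[i, j]
    for i in range(n):
        for j in range(n):
            var += (i - mean) ** 2 * p[i, j]
            hom += p[i, j] / (1 + (i - j) ** 2)
            con += (i - j) ** 2 * p[i, j]
            dis += abs(i - j) * p[i, j]
            if p[i, j] > 0:
                ent -= p[i, j] * math.log(p[i, j])
            sm += p[i, j] ** 2
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * p[i, :].sum() for i in range(n)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * p[:, j].sum() for j in range(n)))
    cross = sum(i * j * p[i, j] for i in range(n) for j in range(n))
    cor = (cross - mu_x * mu_y) / (sd_x * sd_y) if sd_x * sd_y > 0 else float("nan")
    return {"M": mean, "V": var, "H": hom, "Con": con, "D": dis, "E": ent,
            "SM": sm, "Cor": cor}


class TestMeanDN:
    def test_constant_and_two_point_means(self):
        assert mean_dn(pixel_set([[100, 100, 100]] * 4)) == pytest.approx(
            {"R": 100, "G": 100, "B": 100}
        )
        assert mean_dn(pixel_set([[0, 0, 0], [255, 255, 255]]))["R"] == 127.5


class TestColorIndexes:
    def test_achromatic_pixel_zeroes_difference_indexes(self):
        ci = color_indexes(80, 80, 80)
        for name in ("ExG", "NGRDI", "MGRVI", "VARI", "GLA", "RGBVI", "IKAW"):
            assert ci[name] == pytest.approx(0.0, abs=1e-12)

    def test_hand_values_50_150_100(self):
        ci = color_indexes(50, 150, 100)
        assert ci["ExR"] == pytest.approx(1.4 * 50 - 150)      # -80
        assert ci["ExB"] == pytest.approx(1.4 * 100 - 150)     # -10
        assert ci["ExG"] == pytest.approx(2 * 150 - 100 - 50)  # 150
        assert ci["ExGR"] == pytest.approx(150 - (-80))        # 230
        assert ci["VEG"] == pytest.approx(
            150 / (50**0.667 * 100**0.333), rel=1e-12
        )

    def test_zero_denominators_flagged_missing(self):
        ci = color_indexes(120, 120, 60)  # WI denominator R - G = 0
        assert math.isnan(ci["WI"])
        ci = color_indexes(0, 0, 0)
        for name in ("BNI", "GNI", "RNI", "VARI", "NGRDI", "MGRVI"):
            assert math.isnan(ci[name])

    def test_swapping_r_and_b_swaps_bni_rni_and_negates_ikaw(self):
        a = color_indexes(60, 110, 30)
        b = color_indexes(30, 110, 60)
        assert a["BNI"] == pytest.approx(b["RNI"])
        assert a["RNI"] == pytest.approx(b["BNI"])
        assert a["IKAW"] == pytest.approx(-b["IKAW"])

    def test_exactly_fifteen_indexes(self):
        assert list(color_indexes(1, 2, 3)) == CI_NAMES


class TestGLCM:
    def test_two_row_grid_enumeration(self):
        """[[0,0],[1,1]] with offset (0,1): pairs (0,0) and (1,1) only."""
        grid = np.array([[0.0, 0.0], [255.0, 255.0]])
        p = glcm(grid, n_levels=2, offsets=[(0, 1)], symmetric=True)
        assert p[0, 0] == pytest.approx(0.5)
        assert p[1, 1] == pytest.approx(0.5)
        assert p[0, 1] == p[1, 0] == 0.0

    def test_constant_grid_single_cell(self):
        p = glcm(np.full((4, 4), 100.0), n_levels=8)
        k = quantize(np.array(100.0), 8)
        assert p[k, k] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_normalization_on_random_grids(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            grid = rng.uniform(0, 255, (6, 6))
            assert glcm(grid, n_levels=16).sum() == pytest.approx(1.0, abs=1e-9)

    def test_mask_restricts_pairs(self):
        grid = np.array([[0.0, 255.0], [255.0, 0.0]])
        mask = np.array([[True, True], [False, False]])
        p = glcm(grid, mask=mask, n_levels=2, offsets=[(0, 1)])
        oracle = oracle_glcm(quantize(grid, 2), mask, (0, 1), 2, True)
        np.testing.assert_allclose(p, oracle)

    def test_no_valid_pair_is_texture_undefined(self):
        mask = np.array([[True, False], [False, True]])  # no adjacent pair
        assert glcm(np.zeros((2, 2)), mask=mask, offsets=[(0, 1)]) is None
        feats = plot_texture_features(np.zeros((2, 2)), mask=mask, offsets=[(0, 1)])
        assert all(math.isnan(v) for v in feats.values())


class TestTextureFeatures:
    def test_two_level_diagonal_matrix_hand_values(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        f = texture_features(p)
        assert f["Con"] == 0.0
        assert f["D"] == 0.0
        assert f["SM"] == pytest.approx(0.5)
        assert f["E"] == pytest.approx(math.log(2))
        assert f["Cor"] == pytest.approx(1.0)
        assert f["M"] == pytest.approx(0.5)

    def test_degenerate_single_cell_matrix(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        f = texture_features(p)
        assert f["H"] == 1.0
        assert f["SM"] == 1.0
        assert f["E"] == 0.0
        assert math.isnan(f["Cor"])  # zero marginal variance

    def test_entropy_log_base_switch(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert texture_features(p, log_base=2)["E"] == pytest.approx(1.0)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            texture_features(np.array([[0.5, 0.1], [0.1, 0.1]]))  # sums to 0.8

    def test_oracle_equivalence_on_random_grids(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            grid = rng.uniform(0, 255, (8, 8))
            mask = rng.random((8, 8)) > 0.2
            for offset in DEFAULT_OFFSETS:
                levels = quantize(grid, 8)
                expected_p = oracle_glcm(levels, mask, offset, 8, True)
                got = glcm(grid, mask=mask, n_levels=8, offsets=[offset])
                if expected_p is None:
                    assert got is None
                    continue
                np.testing.assert_allclose(got, expected_p, atol=1e-12)
                exp = oracle_textures(expected_p)
                act = texture_features(got)
                for k in exp:
                    assert act[k] == pytest.approx(exp[k], abs=1e-10, nan_ok=True)

    def test_gray_shift_by_whole_bins_shifts_mean_only(self):
        """Adding k bin-widths shifts M by k and leaves Con, D, H unchanged."""
        rng = np.random.default_rng(5)
        grid = rng.uniform(0, 95, (8, 8))  # bin width 256/32 = 8 DN
        a = plot_texture_features(grid, n_levels=32)
        b = plot_texture_features(grid + 3 * 8, n_levels=32)
        assert b["M"] == pytest.approx(a["M"] + 3, abs=1e-10)
        for k in ("Con", "D", "H", "E", "SM", "V"):
            assert b[k] == pytest.approx(a[k], abs=1e-10)


class TestFeatureTable:
    def test_table_has_the_42_rgb_features(self, small_plots):
        table = rgb_feature_table(small_plots)
        assert table.columns.tolist() == ["plot_id"] + RGB_FEATURE_NAMES
        assert len([c for c in table.columns if c in CI_NAMES]) == 15
        assert len([c for c in table.columns if c in TEXTURE_NAMES]) == 24
        assert table.shape[0] == len(small_plots)

    def test_per_pixel_aggregate_matches_mean_first_on_constant_plots(
        self, small_plots
    ):
        a = rgb_feature_table(small_plots, aggregate="mean_first")
        b = rgb_feature_table(small_plots, aggregate="per_pixel")
        # noiseless plots are constant, so the two aggregation orders agree
        for name in ("BNI", "ExG", "NGRDI", "GLA"):
            np.testing.assert_allclose(a[name], b[name], atol=1e-9)

    def test_unknown_aggregate_rejected(self, small_plots):
        with pytest.raises(ValueError):
            rgb_feature_table(small_plots, aggregate="median")
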