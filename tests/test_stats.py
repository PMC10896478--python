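"""Group statistics: GLM oracles, smoothness estimation, cluster machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import ndimage

from fcsconn.grid import MaskedVolumeGrid
from fcsconn.stats import (ClusterCorrectionParams, StatMap, StatsError,
                           estimate_smoothness, extract_clusters,
                           monte_carlo_cluster_threshold,
                           significant_voxel_count, voxelwise_ancova,
                           voxelwise_behaviour_regression)


def _design(n, seed=0):
    r = np.random.default_rng(seed)
    return pd.DataFrame({
        "group": ["patient"] * (n // 2) + ["control"] * (n - n // 2),
        "age": r.normal(68, 8, n),
        "sex": r.integers(0, 2, n),
        "education": r.normal(12, 3, n),
    })


def _line_grid(n):
    return MaskedVolumeGrid(np.ones((n, 1, 1), dtype=bool), 3.0)


class TestVoxelwiseAncova:
    def test_exact_null_gives_zero_t(self):
        design = _design(10)
        # maps constructed with no group effect and no noise: pure covariate
        # structure, perfectly explained by the model
        maps = np.outer(design["age"].to_numpy(), np.ones(4))
        smap = voxelwise_ancova(list(maps), design, _line_grid(4))
        np.testing.assert_allclose(smap.values, 0.0, atol=1e-8)

    def test_single_voxel_matches_normal_equations_oracle(self):
        design = _design(12, seed=5)
        r = np.random.default_rng(8)
        y = r.standard_normal(12)
        smap = voxelwise_ancova(y[:, None], design, _line_grid(1))
        # independent oracle: explicit normal equations + contrast variance
        X = np.column_stack([
            np.ones(12), (design["group"] == "patient").astype(float),
            design["age"], design["sex"], design["education"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        mse = resid @ resid / (12 - 5)
        c = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        t_oracle = beta[1] / np.sqrt(mse * c @ np.linalg.inv(X.T @ X) @ c)
        assert smap.values[0] == pytest.approx(t_oracle, rel=1e-10)
        # cross-check against statsmodels as a second, library oracle
        fit = sm.OLS(y, X).fit()
        assert smap.values[0] == pytest.approx(fit.tvalues[1], rel=1e-8)
        assert smap.df == 7

    def test_duplicating_the_cohort_increases_evidence(self):
        design = _design(12, seed=2)
        r = np.random.default_rng(3)
        y = (r.standard_normal(12)
             + 0.8 * (design["group"] == "patient").to_numpy())
        t1 = voxelwise_ancova(y[:, None], design, _line_grid(1)).values[0]
        doubled = pd.concat([design, design], ignore_index=True)
        y2 = np.concatenate([y, y])
        t2 = voxelwise_ancova(y2[:, None], doubled, _line_grid(1)).values[0]
        assert abs(t2) > abs(t1)
        assert np.sign(t2) == np.sign(t1)

    def test_more_parameters_than_subjects_raises(self):
        design = _design(5)
        design["sex"] = [0, 1, 0, 1, 0]   # keep all five columns informative
        with pytest.raises(StatsError):
            voxelwise_ancova(np.zeros((5, 2)) + np.arange(2), design,
                             _line_grid(2))


class TestBehaviourRegression:
    def test_score_collinear_with_covariate_raises(self):
        design = _design(12, seed=1)
        design["score"] = design["age"]
        with pytest.raises(StatsError, match="rank"):
            voxelwise_behaviour_regression(
                np.random.default_rng(0).standard_normal((12, 3)),
                design, _line_grid(3), "score")

    def test_recovers_planted_positive_association(self):
        r = np.random.default_rng(99)
        design = _design(30, seed=12)
        design["score"] = r.standard_normal(30)
        loading = np.array([1.0, 0.8, 0.0, 0.0])
        maps = (design["score"].to_numpy()[:, None] * loading
                + 0.3 * r.standard_normal((30, 4)))
        smap = voxelwise_behaviour_regression(list(maps), design,
                                              _line_grid(4), "score")
        assert smap.values[0] > smap.voxel_threshold(0.05)
        assert smap.values[1] > smap.voxel_threshold(0.05)
        assert abs(smap.values[2]) < smap.values[0]


class TestSmoothnessEstimation:
    def _maps(self, fwhm_mm, n_maps, grid, seed):
        r = np.random.default_rng(seed)
        sigma = fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / grid.voxel_size_mm
        out = []
        for _ in range(n_maps):
            vol = r.standard_normal(grid.shape)
            if sigma > 0:
                vol = ndimage.gaussian_filter(vol, sigma)
            out.append(vol[grid.mask])
        return np.vstack(out)

    def test_white_noise_reports_about_one_voxel(self):
        grid = MaskedVolumeGrid(np.ones((20, 20, 20), dtype=bool), 3.0)
        est = [estimate_smoothness(self._maps(0.0, 2, grid, s), grid).mean()
               for s in range(10)]
        assert np.mean(est) == pytest.approx(3.0, rel=0.2)

    def test_six_mm_maps_estimated_between_5_and_7(self):
        grid = MaskedVolumeGrid(np.ones((22, 22, 22), dtype=bool), 3.0)
        est = [estimate_smoothness(self._maps(6.0, 4, grid, 100 + s), grid).mean()
               for s in range(10)]
        assert 5.0 <= np.mean(est) <= 7.0

    def test_smoothness_estimate_is_monotone_in_true_smoothing(self):
        grid = MaskedVolumeGrid(np.ones((22, 22, 22), dtype=bool), 3.0)
        wins = 0
        for s in range(10):
            e6 = estimate_smoothness(self._maps(6.0, 3, grid, 200 + s), grid)
            e9 = estimate_smoothness(self._maps(9.0, 3, grid, 300 + s), grid)
            wins += e9.mean() > e6.mean()
        assert wins >= 9

    def test_constant_maps_report_clip_value(self):
        grid = MaskedVolumeGrid(np.ones((8, 8, 8), dtype=bool), 3.0)
        est = estimate_smoothness(np.ones((2, grid.n_voxels)), grid)
        np.testing.assert_allclose(est, 3.0)


class TestMonteCarloThreshold:
    def _grid(self):
        return MaskedVolumeGrid(np.ones((12, 12, 10), dtype=bool), 3.0)

    def test_requires_smoothness(self):
        with pytest.raises(StatsError):
            monte_carlo_cluster_threshold(self._grid(),
                                          ClusterCorrectionParams(), 0)

    def test_alpha_near_one_keeps_almost_any_cluster(self):
        params = ClusterCorrectionParams(alpha=0.999, n_iterations=150,
                                         smoothness_fwhm_mm=(6.0,) * 3)
        ext = monte_carlo_cluster_threshold(self._grid(), params, 0)
        assert ext.n_voxels == ext.max_sizes.min()

    def test_threshold_monotone_in_alpha(self):
        grid = self._grid()
        exts = []
        for alpha in (0.10, 0.05, 0.01):
            params = ClusterCorrectionParams(alpha=alpha, n_iterations=200,
                                             smoothness_fwhm_mm=(6.0,) * 3)
            exts.append(monte_carlo_cluster_threshold(grid, params, 7).n_voxels)
        assert exts[0] <= exts[1] <= exts[2]

    def test_seeded_reproducibility(self):
        params = ClusterCorrectionParams(n_iterations=150,
                                         smoothness_fwhm_mm=(6.0,) * 3)
        a = monte_carlo_cluster_threshold(self._grid(), params, 42)
        b = monte_carlo_cluster_threshold(self._grid(), params, 42)
        assert a.n_voxels == b.n_voxels
        np.testing.assert_array_equal(a.max_sizes, b.max_sizes)

    def test_invalid_params_rejected(self):
        with pytest.raises(StatsError):
            ClusterCorrectionParams(alpha=0.0)
        with pytest.raises(StatsError):
            ClusterCorrectionParams(connectivity=8)


class TestExtractClusters:
    def _stat_map(self, vol, grid, df=20):
        return StatMap(vol[grid.mask], df, grid)

    def test_all_zero_map_gives_empty_table(self):
        grid = MaskedVolumeGrid(np.ones((6, 6, 6), dtype=bool), 3.0)
        table = extract_clusters(self._stat_map(np.zeros(grid.shape), grid),
                                 ClusterCorrectionParams(), 0)
        assert len(table) == 0

    def test_constructed_blobs_filtered_by_extent(self):
        grid = MaskedVolumeGrid(np.ones((10, 10, 4), dtype=bool), 3.0)
        vol = np.zeros(grid.shape)
        vol[1:6, 1:3, 1] = 5.0          # 10-voxel blob
        vol[8, 6:9, 2] = 5.0            # 3-voxel blob
        table = extract_clusters(self._stat_map(vol, grid),
                                 ClusterCorrectionParams(), 5)
        assert len(table) == 1
        assert table.loc[0, "n_voxels"] == 10
        assert table.loc[0, "sign"] == "+"
        assert table.loc[0, "volume_mm3"] == 10 * 27.0

    def test_negative_clusters_report_sign(self):
        grid = MaskedVolumeGrid(np.ones((8, 8, 4), dtype=bool), 3.0)
        vol = np.zeros(grid.shape)
        vol[2:6, 2:6, 1:3] = -4.0
        table = extract_clusters(self._stat_map(vol, grid),
                                 ClusterCorrectionParams(), 3)
        assert set(table["sign"]) == {"-"}
        assert significant_voxel_count(self._stat_map(vol, grid),
                                       ClusterCorrectionParams(), 3) == 32

    def test_connectivity_semantics_on_diagonal_chain(self):
        grid = MaskedVolumeGrid(np.ones((6, 6, 6), dtype=bool), 3.0)
        vol = np.zeros(grid.shape)
        for i in range(5):
            vol[i, i, i] = 6.0          # voxels touch only at corners
        t26 = extract_clusters(self._stat_map(vol, grid),
                               ClusterCorrectionParams(connectivity=26), 0)
        t6 = extract_clusters(self._stat_map(vol, grid),
                              ClusterCorrectionParams(connectivity=6), 0)
        assert len(t26) == 1 and t26.loc[0, "n_voxels"] == 5
        assert len(t6) == 5
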