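"""FCS core: streamed vs dense oracles, conservation, smoothing contracts."""

import numpy as np
import pytest

from conftest import random_mask_grid, random_series
from fcsconn.fcs import (ConnectivityParams, FCSError, FCSMap, aggregate_range,
                         compute_binned_fcs, compute_fcs, smooth_map)
from fcsconn.grid import MaskedVolumeGrid
from fcsconn.preproc import BoldSeries


def dense_fcs_oracle(data, coords, params):
    """Brute-force reference: explicit correlation + distance matrices."""
    n = data.shape[0]
    R = np.corrcoef(data)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)
    R = np.clip(R, -(1 - 1e-7), 1 - 1e-7)
    Z = np.where(R > params.r0, np.arctanh(R), 0.0)
    full = Z.sum(axis=1) / (n - 1)
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    edges = params.bin_edges_mm
    binned = np.zeros((n, params.n_bins))
    for k in range(params.n_bins):
        sel = (D >= edges[k]) & (D < edges[k + 1])
        if k == params.n_bins - 1:
            sel |= D == edges[-1]
        np.fill_diagonal(sel, False)
        binned[:, k] = np.where(sel, Z, 0.0).sum(axis=1) / (n - 1)
    return full, binned


def _toy_params():
    return ConnectivityParams(n_bins=6, bin_width_mm=10.0, distance_max_mm=60.0,
                              short_long_cut_mm=30.0)


def _orthonormal_rows(n, t, seed=3):
    raw = np.random.default_rng(seed).standard_normal((t, n))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    return q.T  # rows orthonormal and mean-free


class TestComputeFCS:
    def test_mutually_orthogonal_series_give_zero(self):
        grid = MaskedVolumeGrid(np.ones((3, 1, 1), dtype=bool), 3.0)
        e = _orthonormal_rows(3, 12)
        out = compute_fcs(BoldSeries(e), grid)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_three_voxel_closed_form(self):
        # r12 = 0.5 exactly, r13 = r23 = 0 -> FCS(1) = FCS(2) = atanh(.5)/2
        grid = MaskedVolumeGrid(np.ones((3, 1, 1), dtype=bool), 3.0)
        e = _orthonormal_rows(3, 16)
        x1 = e[0]
        x2 = 0.5 * e[0] + np.sqrt(0.75) * e[1]
        x3 = e[2]
        out = compute_fcs(BoldSeries(np.vstack([x1, x2, x3])), grid)
        expected = np.arctanh(0.5) / 2.0
        assert out.values[0] == pytest.approx(expected, abs=1e-12)
        assert out.values[1] == pytest.approx(expected, abs=1e-12)
        assert out.values[2] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        grid = random_mask_grid(seed)
        series = random_series(grid, 48, seed=seed + 100)
        params = _toy_params()
        got = compute_fcs(series, grid, params, block_size=16)
        expected, _ = dense_fcs_oracle(series.data, grid.voxel_coordinates_mm,
                                       params)
        np.testing.assert_allclose(got.values, expected, atol=1e-10)

    @pytest.mark.parametrize("block_size", [1, 7, 64, 10_000])
    def test_block_size_independence(self, block_size):
        grid = random_mask_grid(11)
        series = random_series(grid, 40, seed=5)
        ref = compute_fcs(series, grid, _toy_params(), block_size=3)
        got = compute_fcs(series, grid, _toy_params(), block_size=block_size)
        # identical up to BLAS summation-order noise
        np.testing.assert_allclose(got.values, ref.values, atol=1e-12)

    def test_threshold_monotonicity_and_positivity(self):
        for seed in range(5):
            grid = random_mask_grid(seed + 40)
            series = random_series(grid, 32, seed=seed)
            lo = compute_fcs(series, grid, ConnectivityParams(
                r0=0.1, n_bins=6, bin_width_mm=10, distance_max_mm=60,
                short_long_cut_mm=30))
            hi = compute_fcs(series, grid, ConnectivityParams(
                r0=0.4, n_bins=6, bin_width_mm=10, distance_max_mm=60,
                short_long_cut_mm=30))
            assert np.all(hi.values <= lo.values + 1e-15)
            assert np.all(lo.values >= 0.0)

    def test_perfectly_correlated_pair_stays_finite(self):
        grid = MaskedVolumeGrid(np.ones((2, 1, 1), dtype=bool), 3.0)
        x = np.sin(np.arange(20, dtype=float))
        out = compute_fcs(BoldSeries(np.vstack([x, x])), grid)
        assert np.all(np.isfinite(out.values))

    def test_zero_variance_voxel_contributes_nothing(self, rng):
        grid = MaskedVolumeGrid(np.ones((3, 1, 1), dtype=bool), 3.0)
        data = rng.standard_normal((3, 30))
        data[1] = 4.2  # constant voxel
        out = compute_fcs(BoldSeries(data), grid)
        assert out.values[1] == 0.0

    def test_too_small_mask_raises(self):
        grid = MaskedVolumeGrid(np.ones((1, 1, 1), dtype=bool), 3.0)
        with pytest.raises(FCSError):
            compute_fcs(BoldSeries(np.ones((1, 10)) + np.arange(10)), grid)


class TestBinnedFCS:
    def test_single_bin_equals_full_range(self):
        grid = random_mask_grid(7)
        series = random_series(grid, 40, seed=2)
        params = ConnectivityParams(n_bins=1, bin_width_mm=60.0,
                                    distance_max_mm=60.0,
                                    short_long_cut_mm=60.0)
        binned = compute_binned_fcs(series, grid, params)
        full = compute_fcs(series, grid, params)
        np.testing.assert_array_equal(binned.values[:, 0], full.values)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        grid = random_mask_grid(seed + 60)
        series = random_series(grid, 48, seed=seed + 200)
        params = _toy_params()
        got = compute_binned_fcs(series, grid, params, block_size=9)
        _, expected = dense_fcs_oracle(series.data, grid.voxel_coordinates_mm,
                                       params)
        np.testing.assert_allclose(got.values, expected, atol=1e-10)

    def test_row_sums_conserve_full_fcs(self, elongated_grid):
        series = random_series(elongated_grid, 60, seed=9)
        params = ConnectivityParams()     # 18 x 10 mm default layout
        binned = compute_binned_fcs(series, elongated_grid, params)
        full = compute_fcs(series, elongated_grid, params)
        scale = np.maximum(np.abs(full.values), 1e-30)
        assert np.max(np.abs(binned.values.sum(axis=1) - full.values) / scale) \
            < 1e-9

    def test_bin_masks_reflect_neighbour_geometry(self, elongated_grid):
        series = random_series(elongated_grid, 30, seed=1)
        binned = compute_binned_fcs(series, elongated_grid,
                                    ConnectivityParams())
        # every voxel has a 0-10 mm neighbour; only the bar's ends reach the
        # farthest bins
        assert binned.bin_masks[:, 0].all()
        far = binned.bin_masks[:, 11]     # 110-120 mm
        assert 0 < far.sum() < elongated_grid.n_voxels


class TestAggregateRange:
    def test_default_cut_at_100mm_splits_10_and_8_bins(self, elongated_grid):
        series = random_series(elongated_grid, 40, seed=4)
        binned = compute_binned_fcs(series, elongated_grid, ConnectivityParams())
        short, long_ = aggregate_range(binned)
        np.testing.assert_allclose(short.values,
                                   binned.values[:, :10].sum(axis=1), atol=0)
        np.testing.assert_allclose(long_.values,
                                   binned.values[:, 10:].sum(axis=1), atol=0)

    def test_cut_at_max_gives_empty_long_map(self, elongated_grid):
        series = random_series(elongated_grid, 40, seed=4)
        binned = compute_binned_fcs(series, elongated_grid, ConnectivityParams())
        _, long_ = aggregate_range(binned, cut_mm=180.0)
        np.testing.assert_array_equal(long_.values, 0.0)

    def test_short_plus_long_equals_full(self, elongated_grid):
        series = random_series(elongated_grid, 40, seed=6)
        params = ConnectivityParams()
        binned = compute_binned_fcs(series, elongated_grid, params)
        full = compute_fcs(series, elongated_grid, params)
        short, long_ = aggregate_range(binned)
        scale = np.maximum(np.abs(full.values), 1e-30)
        assert np.max(np.abs(short.values + long_.values - full.values)
                      / scale) < 1e-9

    def test_cut_off_a_bin_edge_raises(self, elongated_grid):
        series = random_series(elongated_grid, 30, seed=3)
        binned = compute_binned_fcs(series, elongated_grid, ConnectivityParams())
        with pytest.raises(FCSError):
            aggregate_range(binned, cut_mm=95.0)


class TestParams:
    def test_layout_must_be_consistent(self):
        with pytest.raises(FCSError):
            ConnectivityParams(n_bins=18, bin_width_mm=10.0,
                               distance_max_mm=170.0)
        with pytest.raises(FCSError):
            ConnectivityParams(short_long_cut_mm=95.0)
        with pytest.raises(FCSError):
            ConnectivityParams(r0=1.0)


class TestSmoothing:
    def _big_grid(self):
        return MaskedVolumeGrid(np.ones((21, 21, 21), dtype=bool), 3.0)

    def test_zero_fwhm_is_identity(self, rng):
        grid = self._big_grid()
        fcs_map = FCSMap(rng.random(grid.n_voxels), grid)
        out = smooth_map(fcs_map, 0.0)
        np.testing.assert_array_equal(out.values, fcs_map.values)

    def test_impulse_response_has_6mm_fwhm(self):
        grid = self._big_grid()
        values = np.zeros(grid.n_voxels)
        values[grid.flat_index((10, 10, 10))] = 1.0
        out = smooth_map(FCSMap(values, grid), 6.0).to_volume()
        half = out[10, 10, 10] / 2.0
        x = np.arange(21, dtype=float)
        for profile in (out[:, 10, 10], out[10, :, 10], out[10, 10, :]):
            # interpolate the half-max crossings on each side of the peak
            left = np.interp(half, profile[:11], x[:11])
            right = np.interp(half, profile[10:][::-1], x[10:][::-1])
            width_mm = (right - left) * 3.0
            assert abs(width_mm - 6.0) <= 1.5   # within half a voxel

    def test_constant_map_is_preserved_everywhere(self):
        # mask-weighted smoothing keeps a constant exactly constant,
        # including at the boundary
        grid = self._big_grid()
        out = smooth_map(FCSMap(np.full(grid.n_voxels, 2.5), grid), 6.0)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-10)
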