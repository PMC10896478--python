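"""Functional connectivity strength (FCS): voxel-wise weighted degree centrality.

For voxel *i* on a grey-matter mask of ``N`` voxels,

    FCS(i) = 1/(N - 1) * sum_{j != i, r_ij > r0} z_ij,

where ``r_ij`` is the Pearson correlation of the two voxels' preprocessed
time courses, ``r0`` (default 0.2) discards weak, noise-dominated edges,
and ``z_ij = atanh(r_ij)`` is the Fisher Z transform. The distance-resolved
variant partitions the same sum by the Euclidean distance ``D_ij`` between
voxel coordinates into half-open bins ``[w(k-1), wk)`` (default 18 bins of
10 mm, spanning 0-180 mm); both share the ``1/(N - 1)`` normalization, so
the per-bin maps sum exactly to the full-range map — a conservation law the
tests exploit. Because ``r0 > 0``, only positive correlations ever
contribute and all FCS values are nonnegative.

The pairwise computation is streamed over voxel blocks so the full N x N
correlation matrix is never materialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .grid import MaskedVolumeGrid
from .preproc import BoldSeries

logger = logging.getLogger(__name__)

# r is capped just below 1 before atanh so perfectly correlated voxel pairs
# (possible in noiseless synthetic data) keep FCS finite.
_R_CLAMP = 1.0 - 1e-7

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class FCSError(ValueError):
    pass


@dataclass(frozen=True)
class ConnectivityParams:
    """Thresholds and distance-bin layout for FCS computation."""

    r0: float = 0.2
    bin_width_mm: float = 10.0
    n_bins: int = 18
    distance_max_mm: float = 180.0
    short_long_cut_mm: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r0 < 1.0:
            raise FCSError("r0 must lie in [0, 1)")
        if self.bin_width_mm <= 0 or self.n_bins < 1 or self.distance_max_mm <= 0:
            raise FCSError("bin layout parameters must be positive")
        if not np.isclose(self.n_bins * self.bin_width_mm, self.distance_max_mm):
            raise FCSError(
                f"n_bins * bin_width_mm ({self.n_bins * self.bin_width_mm}) "
                f"!= distance_max_mm ({self.distance_max_mm})"
            )
        edges = self.bin_edges_mm
        if not np.any(np.isclose(edges, self.short_long_cut_mm)):
            raise FCSError(
                f"short_long_cut_mm ({self.short_long_cut_mm}) is not a bin edge"
            )

    @property
    def bin_edges_mm(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width_mm


@dataclass
class FCSMap:
    """One FCS value per in-mask voxel (dimensionless Fisher-Z units)."""

    values: np.ndarray
    grid: MaskedVolumeGrid
    params: ConnectivityParams | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_voxels,):
            raise FCSError(
                f"expected {self.grid.n_voxels} values, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise FCSError("FCS map contains non-finite values")
        self.values = v

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        return self.grid.unmask(self.values, fill)


@dataclass
class BinnedFCSMaps:
    """Voxel x distance-bin decomposition of the FCS map.

    ``bin_masks[:, k]`` marks voxels with at least one in-mask neighbour at
    a distance inside bin ``k``; per-bin group analyses are confined to it
    because peripheral bins cover only part of the mask.
    """

    values: np.ndarray                # (n_voxels, n_bins)
    bin_edges_mm: np.ndarray          # (n_bins + 1,)
    bin_masks: np.ndarray             # (n_voxels, n_bins) bool
    grid: MaskedVolumeGrid
    params: ConnectivityParams = field(default_factory=ConnectivityParams)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_map(self, k: int) -> FCSMap:
        return FCSMap(self.values[:, k].copy(), self.grid, self.params)


def _standardized_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean and unit-norm rows; zero-variance rows become zero vectors.

    A zero row yields correlation 0 with everything (never exceeding r0),
    the documented policy for degenerate voxels; their indices are logged.
    """
    d = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(d, axis=1)
    flat = norms == 0.0
    if np.any(flat):
        logger.warning(
            "%d zero-variance voxel(s) flagged; correlations set to 0: %s",
            flat.sum(), np.flatnonzero(flat)[:20],
        )
        norms = np.where(flat, 1.0, norms)
    return d / norms[:, None], flat


def _check_inputs(series: BoldSeries, grid: MaskedVolumeGrid) -> None:
    if grid.n_voxels < 2:
        raise FCSError("FCS needs at least 2 mask voxels")
    if series.n_voxels != grid.n_voxels:
        raise FCSError(
            f"series rows ({series.n_voxels}) != mask voxels ({grid.n_voxels})"
        )


def _block_slices(n: int, block_size: int):
    block_size = max(1, int(block_size))
    for start in range(0, n, block_size):
        yield slice(start, min(start + block_size, n))


def compute_fcs(series: BoldSeries, grid: MaskedVolumeGrid,
                params: ConnectivityParams | None = None,
                block_size: int = 256) -> FCSMap:
    """Full-range FCS map, streamed over voxel blocks.

    Only pairs with ``r_ij`` strictly above ``params.r0`` contribute; the
    result is identical for any block size.
    """
    params = params or ConnectivityParams()
    _check_inputs(series, grid)
    Z, _ = _standardized_rows(series.data)
    n = grid.n_voxels
    out = np.empty(n)
    for blk in _block_slices(n, block_size):
        R = Z[blk] @ Z.T
        R[np.arange(R.shape[0]), np.arange(blk.start, blk.stop)] = 0.0
        np.clip(R, -_R_CLAMP, _R_CLAMP, out=R)
        contrib = np.where(R > params.r0, np.arctanh(R), 0.0)
        out[blk] = contrib.sum(axis=1) / (n - 1)
    return FCSMap(out, grid, params)


def compute_binned_fcs(series: BoldSeries, grid: MaskedVolumeGrid,
                       params: ConnectivityParams | None = None,
                       block_size: int = 256) -> BinnedFCSMaps:
    """Distance-binned FCS maps sharing the full-range 1/(N-1) normalization.

    Bins are half-open ``[edge_k, edge_{k+1})``; a pair at exactly the
    maximum distance (possible only if the bin span understates the mask
    diameter by zero margin) is assigned to the last bin, and pairs beyond
    the last edge fall in no bin.
    """
    params = params or ConnectivityParams()
    _check_inputs(series, grid)
    Z, _ = _standardized_rows(series.data)
    n = grid.n_voxels
    edges = params.bin_edges_mm
    n_bins = params.n_bins
    coords = grid.voxel_coordinates_mm
    values = np.zeros((n, n_bins))
    neighbour_counts = np.zeros((n, n_bins), dtype=np.int64)
    for blk in _block_slices(n, block_size):
        R = Z[blk] @ Z.T
        rows = np.arange(R.shape[0])
        diag = np.arange(blk.start, blk.stop)
        R[rows, diag] = 0.0
        np.clip(R, -_R_CLAMP, _R_CLAMP, out=R)
        contrib = np.where(R > params.r0, np.arctanh(R), 0.0)
        D = cdist(coords[blk], coords)
        k = np.searchsorted(edges, D, side="right") - 1
        k[D == edges[-1]] = n_bins - 1      # documented closed-top dialect
        k[rows, diag] = -1                  # self-pairs fall in no bin
        for b in range(n_bins):
            in_bin = k == b
            values[blk, b] = np.where(in_bin, contrib, 0.0).sum(axis=1) / (n - 1)
            neighbour_counts[blk, b] = in_bin.sum(axis=1)
    return BinnedFCSMaps(values, edges, neighbour_counts > 0, grid, params)


def aggregate_range(binned: BinnedFCSMaps,
                    cut_mm: float | None = None) -> tuple[FCSMap, FCSMap]:
    """Sum bins below / at-or-above ``cut_mm`` into short- and long-range maps.

    ``cut_mm`` must coincide with a bin edge (default: the params' 100 mm
    short/long cut). short + long reproduces the full-range map exactly.
    """
    params = binned.params
    cut = params.short_long_cut_mm if cut_mm is None else cut_mm
    edges = binned.bin_edges_mm
    matches = np.isclose(edges, cut)
    if not matches.any():
        raise FCSError(f"cut {cut} mm is not a bin edge of {edges}")
    k_cut = int(np.flatnonzero(matches)[0])
    short = binned.values[:, :k_cut].sum(axis=1)
    long = binned.values[:, k_cut:].sum(axis=1)
    return (FCSMap(short, binned.grid, params), FCSMap(long, binned.grid, params))


def smooth_volume(values: np.ndarray, grid: MaskedVolumeGrid,
                  fwhm_mm: float) -> np.ndarray:
    """Mask-weighted 3D Gaussian smoothing of a masked-voxel vector.

    The convolution runs on the full grid with zeros outside the mask and
    is renormalized by the smoothed mask indicator inside the mask, so
    boundary voxels are not dimmed by out-of-mask zeros.
    """
    if fwhm_mm < 0:
        raise FCSError("fwhm_mm must be nonnegative")
    if 0 < fwhm_mm < grid.voxel_size_mm:
        logger.info("smoothing FWHM %.2f mm is below the voxel size %.2f mm",
                    fwhm_mm, grid.voxel_size_mm)
    sigma_vox = fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / grid.voxel_size_mm
    vol = grid.unmask(values, 0.0)
    if sigma_vox == 0.0:
        return values.astype(float).copy()
    num = ndimage.gaussian_filter(vol, sigma_vox)
    den = ndimage.gaussian_filter(grid.mask.astype(float), sigma_vox)
    return num[grid.mask] / den[grid.mask]


def smooth_map(fcs_map: FCSMap, fwhm_mm: float = 6.0) -> FCSMap:
    """Gaussian-smooth an FCS map (default 6 mm FWHM, applied to maps only,
    never to time series)."""
    return FCSMap(smooth_volume(fcs_map.values, fcs_map.grid, fwhm_mm),
                  fcs_map.grid, fcs_map.params)
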