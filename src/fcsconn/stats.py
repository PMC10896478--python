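"""Voxel-wise group statistics with Monte Carlo cluster-extent correction.

The group comparison is a one-way ANCOVA, implemented exactly as the
equivalent linear model ``FCS ~ intercept + group + age + sex + education``
with the signed group contrast (patient minus control) reported per voxel.
Family-wise error over the mask is controlled by the classic Monte Carlo
(AlphaSim-style) recipe: simulate smooth Gaussian null fields confined to
the analysis mask, threshold two-sided at the voxel-level p, record the
largest suprathreshold cluster per iteration, and take the empirical
(1 - alpha) quantile of those maxima as the minimum cluster extent. Only
clusters strictly larger than the extent survive. Positive and negative
suprathreshold voxels are clustered separately so each surviving cluster
carries the sign of the group difference.

Brain-behaviour maps use the same machinery with the behavioural composite
score as the regressor of interest within the patient group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .fcs import FCSMap, smooth_volume
from .grid import MaskedVolumeGrid
from .preproc import PreprocError, _check_full_rank

logger = logging.getLogger(__name__)

ANCOVA_COVARIATES = ("age", "sex", "education")


class StatsError(ValueError):
    pass


@dataclass
class StatMap:
    """Voxel-wise test-statistic field on an analysis mask.

    ``analysis_mask`` is a boolean over the grid's masked voxels (the full
    grey-matter mask or one distance-bin mask); statistics are finite on it
    and zero outside.
    """

    values: np.ndarray
    df: int
    grid: MaskedVolumeGrid
    analysis_mask: np.ndarray | None = None
    stat: str = "t"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.analysis_mask is None:
            self.analysis_mask = np.ones(v.shape, dtype=bool)
        if not np.all(np.isfinite(v[self.analysis_mask])):
            raise StatsError("non-finite statistics on the analysis mask")
        self.values = np.where(self.analysis_mask, v, 0.0)

    def voxel_threshold(self, voxel_p: float) -> float:
        """Two-sided critical value at the voxel-level p."""
        if self.stat == "t":
            return float(sps.t.isf(voxel_p / 2.0, self.df))
        return float(sps.norm.isf(voxel_p / 2.0))


@dataclass(frozen=True)
class ClusterCorrectionParams:
    voxel_p: float = 0.05
    alpha: float = 0.05
    n_iterations: int = 1000
    connectivity: int = 26
    smoothness_fwhm_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.voxel_p < 1.0 and 0.0 < self.alpha < 1.0):
            raise StatsError("voxel_p and alpha must lie strictly in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise StatsError("connectivity must be one of 6, 18, 26")
        if self.n_iterations < 100:
            logger.warning("n_iterations=%d < 100; extent quantile will be noisy",
                           self.n_iterations)


@dataclass
class ClusterExtent:
    """Minimum surviving cluster extent from the Monte Carlo null."""

    n_voxels: int
    volume_mm3: float
    max_sizes: np.ndarray = field(repr=False, default=None)


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def stack_maps(maps) -> np.ndarray:
    """(n_subjects, n_voxels) array from FCSMaps / vectors."""
    rows = [m.values if isinstance(m, FCSMap) else np.asarray(m, float)
            for m in maps]
    return np.vstack(rows)


def build_design(design: pd.DataFrame, effect: str,
                 covariates=ANCOVA_COVARIATES) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix [intercept, effect, covariates...] and effect contrast.

    ``group`` columns may be string-labelled (``patient``/``control``) or
    already binary; patients are coded 1 so the contrast is patient minus
    control.
    """
    cols, labels = [np.ones(len(design))], ["intercept"]
    for name in (effect, *covariates):
        col = design[name]
        if name == "group" and col.dtype == object:
            col = (col == "patient").astype(float)
        col = np.asarray(col, dtype=float)
        if name != effect and np.ptp(col) == 0.0:
            # a covariate constant over these subjects carries nothing
            # beyond the intercept (e.g. a single-sex subgroup)
            logger.info("dropping constant covariate %r", name)
            continue
        cols.append(col)
        labels.append(name)
    X = np.column_stack(cols)
    try:
        _check_full_rank(X, labels)
    except PreprocError as exc:
        raise StatsError(str(exc)) from exc
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return X, contrast, labels


def glm_contrast_t(Y: np.ndarray, X: np.ndarray,
                   contrast: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Least-squares fit of Y (n x V) on X; returns (t, df, residuals).

    The t statistic is ``c'b / sqrt(mse * c'(X'X)^-1 c)``; voxels with an
    exactly zero numerator and zero residual variance report t = 0.
    """
    n, p = X.shape
    if Y.shape[0] != n:
        raise StatsError(f"Y has {Y.shape[0]} rows but design has {n}")
    if n <= p:
        raise StatsError(f"need more subjects ({n}) than parameters ({p})")
    # QR keeps the fit stable for covariates on raw scales (age in years etc.)
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta
    df = n - p
    mse = (resid ** 2).sum(axis=0) / df
    # an (almost) exact fit means no residual evidence: report t = 0 rather
    # than a ratio of rounding errors
    scale = np.maximum((Y ** 2).mean(axis=0), 1e-300)
    mse = np.where(mse < 1e-20 * scale, 0.0, mse)
    c_var = float(np.sum(np.linalg.solve(R.T, contrast) ** 2))
    num = contrast @ beta
    den = np.sqrt(mse * c_var)
    t = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return t, df, resid


def voxelwise_ancova(maps, design: pd.DataFrame,
                     grid: MaskedVolumeGrid,
                     covariates=ANCOVA_COVARIATES,
                     analysis_mask: np.ndarray | None = None,
                     return_residuals: bool = False):
    """Signed group-effect t map (patient minus control) with covariates."""
    Y = stack_maps(maps)
    X, contrast, _ = build_design(design, "group", covariates)
    t, df, resid = glm_contrast_t(Y, X, contrast)
    smap = StatMap(t, df, grid, analysis_mask)
    if return_residuals:
        return smap, resid
    return smap


def voxelwise_behaviour_regression(maps, design: pd.DataFrame,
                                   grid: MaskedVolumeGrid,
                                   score: str,
                                   covariates=ANCOVA_COVARIATES,
                                   analysis_mask: np.ndarray | None = None) -> StatMap:
    """t map for a behavioural composite score within one group.

    Positive t means higher FCS with better performance. Callers pass the
    patient-subset design; the function itself is group-agnostic.
    """
    Y = stack_maps(maps)
    X, contrast, _ = build_design(design, score, covariates)
    t, df, _ = glm_contrast_t(Y, X, contrast)
    return StatMap(t, df, grid, analysis_mask)


def estimate_smoothness(residuals: np.ndarray, grid: MaskedVolumeGrid,
                        max_lag: int = 4) -> np.ndarray:
    """Per-axis FWHM (mm) of residual maps from spatial autocorrelation.

    For standardized residuals with Gaussian spatial autocorrelation, the
    lag-``k`` correlation along an axis satisfies
    ``rho_k = 1 - var(diff_k)/2``, giving ``sigma^2 = -k^2 / (4 ln rho_k)``
    in voxel units. Real residual fields often carry heavier-than-Gaussian
    autocorrelation tails, for which a lag-1 fit understates the effective
    smoothness that governs null cluster sizes; the estimate therefore
    takes the largest Gaussian-equivalent sigma over lags 1..``max_lag``
    (restricted to lags with ``rho_k > 0.05``). On truly Gaussian fields
    every lag yields the same sigma, so nothing changes there. Estimates
    are averaged across maps and clipped below at one voxel size (white
    noise has no resolvable smoothness).
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    if residuals.shape[0] < 2:
        raise StatsError("need at least 2 residual maps")
    fwhm = np.empty(3)
    vols = grid.unmask(residuals, np.nan)
    sds = np.nanstd(vols, axis=(1, 2, 3), keepdims=True)
    flat = sds[:, 0, 0, 0] == 0
    if np.any(flat):
        logger.warning("%d constant residual map(s); reporting clip value",
                       flat.sum())
        sds[flat] = 1.0
    vols = vols / sds
    for axis in range(3):
        best = 0.0
        for lag in range(1, max_lag + 1):
            if vols.shape[axis + 1] <= lag:
                continue
            take = [slice(None)] * 4
            drop = [slice(None)] * 4
            take[axis + 1] = slice(lag, None)
            drop[axis + 1] = slice(None, -lag)
            d = vols[tuple(take)] - vols[tuple(drop)]
            with np.errstate(invalid="ignore"):
                dvar = np.nanvar(d, axis=(1, 2, 3))
            rho = np.nanmean(1.0 - dvar / 2.0)
            if 0.05 < rho < 1.0:
                best = max(best, np.sqrt(-lag ** 2 / (4.0 * np.log(rho))))
        fwhm[axis] = best * 2.0 * np.sqrt(2.0 * np.log(2.0)) * grid.voxel_size_mm
    return np.maximum(fwhm, grid.voxel_size_mm)


def _null_max_cluster_size(grid: MaskedVolumeGrid, fwhm_mm, voxel_p: float,
                           structure: np.ndarray,
                           rng: np.random.Generator) -> int:
    """Max suprathreshold cluster size of one smooth Gaussian null field."""
    fwhm_mm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    noise = rng.standard_normal(grid.shape)
    vals = _smooth_full_masked(noise, grid, fwhm_mm)
    z = (vals - vals.mean()) / vals.std()
    thr = sps.norm.isf(voxel_p / 2.0)
    best = 0
    for signed in (z > thr, z < -thr):
        vol = grid.unmask(signed.astype(float), 0.0) > 0.5
        labels, n = ndimage.label(vol, structure=structure)
        if n:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def _smooth_full_masked(volume: np.ndarray, grid: MaskedVolumeGrid,
                        fwhm_mm: np.ndarray) -> np.ndarray:
    """Mask-weighted anisotropic smoothing of a full-grid volume; returns
    masked-voxel values."""
    sigma = fwhm_mm / grid.voxel_size_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if np.all(sigma == 0):
        return volume[grid.mask].astype(float)
    masked = np.where(grid.mask, volume, 0.0)
    num = ndimage.gaussian_filter(masked, sigma)
    den = ndimage.gaussian_filter(grid.mask.astype(float), sigma)
    return num[grid.mask] / den[grid.mask]


def monte_carlo_cluster_threshold(grid: MaskedVolumeGrid,
                                  params: ClusterCorrectionParams,
                                  rng: np.random.Generator | int | None = None
                                  ) -> ClusterExtent:
    """Minimum cluster extent controlling family-wise error at ``alpha``.

    Simulates ``n_iterations`` white-noise volumes, smooths each to the
    supplied per-axis FWHM within the mask, thresholds two-sided at
    ``voxel_p`` and returns the (1 - alpha) 'higher' quantile of the null
    max-cluster-size distribution (in voxels and mm^3). Seeded and
    reproducible.
    """
    if params.smoothness_fwhm_mm is None:
        raise StatsError("smoothness_fwhm_mm must be set (use estimate_smoothness)")
    rng = np.random.default_rng(rng)
    structure = _structure(params.connectivity)
    sizes = np.array([
        _null_max_cluster_size(grid, params.smoothness_fwhm_mm, params.voxel_p,
                               structure, rng)
        for _ in range(params.n_iterations)
    ])
    k = int(np.quantile(sizes, 1.0 - params.alpha, method="higher"))
    return ClusterExtent(k, k * grid.voxel_size_mm ** 3, sizes)


def extract_clusters(stat_map: StatMap, params: ClusterCorrectionParams,
                     extent: ClusterExtent | int) -> pd.DataFrame:
    """Suprathreshold clusters strictly larger than the extent threshold.

    Binarizes two-sided at ``params.voxel_p``, labels positive and negative
    components separately under the configured connectivity, and reports
    per cluster: voxel count, volume in mm^3, peak statistic, peak voxel
    index and mm coordinate, and the sign of the group difference. An empty
    table is a valid outcome.
    """
    k_min = extent.n_voxels if isinstance(extent, ClusterExtent) else int(extent)
    grid = stat_map.grid
    thr = stat_map.voxel_threshold(params.voxel_p)
    structure = _structure(params.connectivity)
    vol = grid.unmask(np.where(stat_map.analysis_mask, stat_map.values, 0.0), 0.0)
    rows = []
    for sign, supra in (("+", vol > thr), ("-", vol < -thr)):
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            idx = labels == lab
            size = int(idx.sum())
            if size <= k_min:
                continue
            stats_vals = vol[idx]
            peak_flat = np.abs(stats_vals).argmax()
            peak_ijk = np.argwhere(idx)[peak_flat]
            rows.append({
                "n_voxels": size,
                "volume_mm3": size * grid.voxel_size_mm ** 3,
                "peak_stat": float(stats_vals[peak_flat]),
                "peak_i": int(peak_ijk[0]), "peak_j": int(peak_ijk[1]),
                "peak_k": int(peak_ijk[2]),
                "peak_x_mm": float(peak_ijk[0] * grid.voxel_size_mm),
                "peak_y_mm": float(peak_ijk[1] * grid.voxel_size_mm),
                "peak_z_mm": float(peak_ijk[2] * grid.voxel_size_mm),
                "sign": sign,
            })
    table = pd.DataFrame(rows, columns=[
        "n_voxels", "volume_mm3", "peak_stat", "peak_i", "peak_j", "peak_k",
        "peak_x_mm", "peak_y_mm", "peak_z_mm", "sign",
    ])
    table = table.sort_values("n_voxels", ascending=False, ignore_index=True)
    table.insert(0, "cluster_id", np.arange(1, len(table) + 1))
    return table


def significant_voxel_count(stat_map: StatMap, params: ClusterCorrectionParams,
                            extent: ClusterExtent | int) -> int:
    """Total voxels inside clusters surviving the extent threshold."""
    table = extract_clusters(stat_map, params, extent)
    return int(table["n_voxels"].sum()) if len(table) else 0
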