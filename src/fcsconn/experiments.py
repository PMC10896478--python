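"""Ground-truth recovery experiments on scaled synthetic cohorts.

These are the package's evaluation harnesses: each function builds a small,
fixed study design (grid, cohort size, planted effect), runs the full
analysis path through the public API, and measures how well the known
ground truth is recovered — family-wise error calibration of the Monte
Carlo cluster correction, distance-specific detection of the planted
long-range disruption, and voxel-wise brain-behaviour recovery. The same
routines back the test suite and the reproduction script, so reported
numbers always come from live computation.

The study grid used for recovery experiments is a 56 x 12 x 10 ellipsoid at
3 mm (~2500 grey-matter voxels, maximum in-mask distance ~150 mm) with two
hub pairs near the ends of the long axis; three of the six hub pairs lie
beyond the 100 mm long-range cut (108, 108 and 132 mm), so every hub
participates in long-range coupling while the within-pair couplings
(24 mm) and one mid-range coupling (84 mm) stay below the cut.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .fcs import (ConnectivityParams, FCSMap, aggregate_range,
                  compute_binned_fcs, smooth_map)
from .grid import MaskedVolumeGrid
from .preproc import BoldSeries, bandpass_filter, preprocess
from .stats import (ClusterCorrectionParams, _null_max_cluster_size, _structure,
                    estimate_smoothness, extract_clusters,
                    monte_carlo_cluster_threshold, significant_voxel_count,
                    voxelwise_ancova, voxelwise_behaviour_regression)
from .synthetic import (LINKED_DOMAIN, SimulationConfig, hub_mask, make_mask,
                        simulate_cohort_table, simulate_subject_bold)

RECOVERY_GRID = (56, 12, 10)
RECOVERY_HUBS = ((4, 5, 4), (12, 5, 4), (40, 5, 4), (48, 5, 4))


def recovery_config(seed: int, *, attenuation: float = 0.5,
                    n_patients: int = 12, n_controls: int = 12,
                    n_timepoints: int = 160,
                    cognition_effect: float = 1.0) -> SimulationConfig:
    """The fixed scaled-down study design used by the recovery experiments."""
    return SimulationConfig(
        grid_shape=RECOVERY_GRID,
        n_timepoints=n_timepoints,
        n_patients=n_patients,
        n_controls=n_controls,
        hub_centers=RECOVERY_HUBS,
        long_range_attenuation=attenuation,
        cognition_effect=cognition_effect,
        seed=seed,
    )


def _subject_maps(config: SimulationConfig, grid: MaskedVolumeGrid, idx: int,
                  params: ConnectivityParams, fwhm_mm: float = 6.0):
    """Simulate, preprocess and map one subject; returns (binned, smoothed
    full / short / long maps)."""
    series, _ = simulate_subject_bold(config, config.subject_group(idx), idx, grid)
    clean, _ = preprocess(series, n_discard=10, low_hz=config.band_hz[0],
                          high_hz=config.band_hz[1])
    binned = compute_binned_fcs(clean, grid, params)
    full = FCSMap(binned.values.sum(axis=1), grid, params)
    short, long_ = aggregate_range(binned)
    return (binned,
            smooth_map(full, fwhm_mm),
            smooth_map(short, fwhm_mm),
            smooth_map(long_, fwhm_mm))


def _bin_extents(grid: MaskedVolumeGrid, bin_masks: np.ndarray,
                 cluster: ClusterCorrectionParams, rng, min_voxels: int = 30):
    """Per-bin Monte Carlo extent thresholds, computed once per geometry."""
    extents = {}
    for k in range(bin_masks.shape[1]):
        bmask = bin_masks[:, k]
        if bmask.sum() < min_voxels:
            continue
        sub = MaskedVolumeGrid(grid.unmask(bmask.astype(float)) > 0.5,
                               grid.voxel_size_mm, name=f"bin-{k}")
        extents[k] = monte_carlo_cluster_threshold(sub, cluster, rng)
    return extents


def fwe_calibration(seed: int, *, grid_shape=(20, 20, 18), fwhm_mm: float = 6.0,
                    n_iterations: int = 1000, n_null: int = 300,
                    voxel_p: float = 0.05, alpha: float = 0.05) -> dict:
    """Family-wise error of the Monte Carlo extent threshold on fresh nulls.

    Derives the extent threshold from ``n_iterations`` null fields on an
    ~2700-voxel mask smoothed to ``fwhm_mm``, then applies it to ``n_null``
    fresh null fields and reports the observed rejection rate together
    with the binomial 95% interval around ``alpha``.
    """
    grid = make_mask(SimulationConfig(grid_shape=grid_shape, seed=seed))
    cluster = ClusterCorrectionParams(voxel_p=voxel_p, alpha=alpha,
                                      n_iterations=n_iterations,
                                      smoothness_fwhm_mm=(fwhm_mm,) * 3)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    extent = monte_carlo_cluster_threshold(grid, cluster, rng)
    structure = _structure(cluster.connectivity)
    hits = 0
    for _ in range(n_null):
        size = _null_max_cluster_size(grid, cluster.smoothness_fwhm_mm,
                                      voxel_p, structure, rng)
        hits += size > extent.n_voxels
    lo, hi = sps.binom.interval(0.95, n_null, alpha)
    return {
        "rate": hits / n_null,
        "n_null": n_null,
        "alpha": alpha,
        "extent_voxels": extent.n_voxels,
        "ci_low": lo / n_null,
        "ci_high": hi / n_null,
        "mask_voxels": grid.n_voxels,
    }


def distance_recovery(seed: int, *, n_cohorts: int = 10,
                      n_per_group: int = 16, attenuation: float = 0.5,
                      mc_iterations: int = 500, fwhm_mm: float = 6.0) -> dict:
    """Detect the planted long-range disruption bin by bin (Fig.-2B-style).

    For each seeded cohort: per-bin ANCOVA within the bin masks with
    cluster correction, then check that the significant-voxel count peaks
    in a bin wholly above the 100 mm cut and that the mean group effect at
    planted hub voxels is negative (patients lower).
    """
    base = recovery_config(seed, attenuation=attenuation,
                           n_patients=n_per_group, n_controls=n_per_group)
    grid = make_mask(base)
    params = ConnectivityParams()
    hubs = grid.mask_values(hub_mask(base, grid))

    # Calibration cohort: its ANCOVA residuals set the null-field smoothness,
    # and the bin geometry (hence per-bin extent thresholds) is shared by
    # every cohort on this grid.
    calib_table = simulate_cohort_table(base, grid)
    calib = [_subject_maps(base, grid, idx, params, fwhm_mm)
             for idx in range(base.n_subjects)]
    probe = calib[0][0]
    _, resid = voxelwise_ancova([m[1] for m in calib], calib_table, grid,
                                return_residuals=True)
    est_fwhm = estimate_smoothness(resid, grid)
    cluster = ClusterCorrectionParams(n_iterations=mc_iterations,
                                      smoothness_fwhm_mm=tuple(est_fwhm))
    mc_rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    extents = _bin_extents(grid, probe.bin_masks, cluster, mc_rng)

    edges = params.bin_edges_mm
    peak_above, negative_effect, per_cohort_counts = [], [], []
    for c in range(n_cohorts):
        cfg = recovery_config(seed + 1000 + c, attenuation=attenuation,
                              n_patients=n_per_group, n_controls=n_per_group)
        table = simulate_cohort_table(cfg, grid)
        binned_all, full_all = [], []
        for idx in range(cfg.n_subjects):
            binned, full, _, _ = _subject_maps(cfg, grid, idx, params, fwhm_mm)
            binned_all.append(binned)
            full_all.append(full)
        counts = np.zeros(params.n_bins, dtype=int)
        for k, extent in extents.items():
            maps_k = [smooth_map(b.bin_map(k), fwhm_mm) for b in binned_all]
            smap_k = voxelwise_ancova(maps_k, table, grid,
                                      analysis_mask=binned_all[0].bin_masks[:, k])
            counts[k] = significant_voxel_count(smap_k, cluster, extent)
        per_cohort_counts.append(counts.tolist())
        peak = int(np.argmax(counts))
        peak_above.append(counts[peak] > 0 and edges[peak] >= base.long_range_cut_mm)

        stack = np.vstack([m.values for m in full_all])
        pat = table["group"].to_numpy() == "patient"
        diff = stack[pat].mean(axis=0) - stack[~pat].mean(axis=0)
        negative_effect.append(float(diff[hubs].mean()) < 0.0)
    return {
        "n_cohorts": n_cohorts,
        "peak_above_cut_fraction": float(np.mean(peak_above)),
        "hub_effect_negative_fraction": float(np.mean(negative_effect)),
        "per_cohort_bin_counts": per_cohort_counts,
        "bin_edges_mm": edges.tolist(),
        "estimated_smoothness_fwhm_mm": [float(f) for f in est_fwhm],
    }


def behaviour_recovery(seed: int, *, n_patients: int = 32,
                       cognition_effect: float = 1.0,
                       n_permutations: int = 20, voxel_p: float = 0.05,
                       fwhm_mm: float = 6.0) -> dict:
    """Voxel-wise brain-behaviour regression against planted ground truth.

    Long-range FCS of the patient group is regressed on the linked
    cognitive score (age, sex, education as covariates). Reports the
    fraction of planted hub voxels (hubs participating in >100 mm pairs)
    with significant positive t, and the mean suprathreshold fraction
    under permuted scores (the empirical false-positive rate, which should
    sit near ``voxel_p``).
    """
    cfg = recovery_config(seed + 77, n_patients=n_patients, n_controls=2,
                          cognition_effect=cognition_effect)
    grid = make_mask(cfg)
    params = ConnectivityParams()
    table = simulate_cohort_table(cfg, grid)
    patients = table[table["group"] == "patient"]
    long_maps = []
    for idx in range(cfg.n_patients):
        _, _, _, long_ = _subject_maps(cfg, grid, idx, params, fwhm_mm)
        long_maps.append(long_)

    smap = voxelwise_behaviour_regression(long_maps, patients, grid,
                                          LINKED_DOMAIN)
    t_crit = smap.voxel_threshold(voxel_p)

    centers = cfg.resolved_hub_centers(grid)
    far = cfg.long_range_cut_mm
    dist = np.linalg.norm(
        (centers[:, None, :] - centers[None, :, :]) * cfg.voxel_size_mm, axis=-1)
    long_range_hubs = centers[np.any(dist > far, axis=1)]
    planted = grid.mask_values(hub_mask(cfg, grid, long_range_hubs))
    planted_frac = float((smap.values[planted] > t_crit).mean())

    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    fp = []
    for _ in range(n_permutations):
        shuffled = patients.copy()
        shuffled[LINKED_DOMAIN] = rng.permutation(
            shuffled[LINKED_DOMAIN].to_numpy())
        null_map = voxelwise_behaviour_regression(long_maps, shuffled, grid,
                                                  LINKED_DOMAIN)
        fp.append(float((np.abs(null_map.values) > t_crit).mean()))
    return {
        "n_patients": n_patients,
        "planted_voxels": int(planted.sum()),
        "planted_significant_fraction": planted_frac,
        "permuted_fp_rate": float(np.mean(fp)),
        "voxel_p": voxel_p,
        "t_critical": t_crit,
    }


def null_cohort_fwe(seed: int, *, n_replicates: int = 20, n_per_group: int = 8,
                    n_timepoints: int = 120, mc_iterations: int = 500,
                    fwhm_mm: float = 6.0) -> dict:
    """Fraction of null cohorts (attenuation = 1) with an empty corrected map.

    The extent threshold is derived once for the shared grid geometry and
    applied to every replicate's full-range group comparison.
    """
    base = recovery_config(seed, attenuation=1.0, n_patients=n_per_group,
                           n_controls=n_per_group, n_timepoints=n_timepoints)
    grid = make_mask(base)
    params = ConnectivityParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    empty, extents = [], []
    for rep in range(n_replicates):
        cfg = recovery_config(seed + 5000 + rep, attenuation=1.0,
                              n_patients=n_per_group, n_controls=n_per_group,
                              n_timepoints=n_timepoints)
        table = simulate_cohort_table(cfg, grid)
        maps = [_subject_maps(cfg, grid, idx, params, fwhm_mm)[1]
                for idx in range(cfg.n_subjects)]
        smap, resid = voxelwise_ancova(maps, table, grid, return_residuals=True)
        cluster = ClusterCorrectionParams(
            n_iterations=mc_iterations,
            smoothness_fwhm_mm=tuple(estimate_smoothness(resid, grid)))
        extent = monte_carlo_cluster_threshold(grid, cluster, rng)
        clusters = extract_clusters(smap, cluster, extent)
        empty.append(len(clusters) == 0)
        extents.append(extent.n_voxels)
    return {
        "n_replicates": n_replicates,
        "empty_fraction": float(np.mean(empty)),
        "extent_voxels": extents,
    }


def filter_gains(repetition_time_s: float = 2.0, n_timepoints: int = 512) -> dict:
    """Amplitude gain of the band-pass at a pass-band (0.05 Hz) and a
    stop-band (0.2 Hz) sinusoid, measured on interior samples."""
    t = np.arange(n_timepoints) * repetition_time_s
    interior = slice(n_timepoints // 4, 3 * n_timepoints // 4)
    out = {}
    for label, freq in (("passband_0.05hz", 0.05), ("stopband_0.2hz", 0.2)):
        series = BoldSeries(np.sin(2 * np.pi * freq * t)[None, :],
                            repetition_time_s)
        filtered = bandpass_filter(series).data[0]
        gain = (np.abs(filtered[interior]).max()
                / np.abs(series.data[0][interior]).max())
        out[label] = float(gain)
    return out


def dense_reference_fcs(series: BoldSeries, grid: MaskedVolumeGrid,
                        params: ConnectivityParams):
    """Dense-matrix reference for FCS and binned FCS (small masks only).

    Forms the full correlation and distance matrices explicitly; used as
    the comparison point for the streamed implementation.
    """
    n = grid.n_voxels
    R = np.corrcoef(series.data)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)
    R = np.clip(R, -(1 - 1e-7), 1 - 1e-7)
    Z = np.where(R > params.r0, np.arctanh(R), 0.0)
    full = Z.sum(axis=1) / (n - 1)
    coords = grid.voxel_coordinates_mm
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    edges = params.bin_edges_mm
    binned = np.zeros((n, params.n_bins))
    for k in range(params.n_bins):
        in_bin = (D >= edges[k]) & (D < edges[k + 1])
        if k == params.n_bins - 1:
            in_bin |= D == edges[-1]
        np.fill_diagonal(in_bin, False)
        binned[:, k] = np.where(in_bin, Z, 0.0).sum(axis=1) / (n - 1)
    return full, binned
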