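"""End-to-end pipeline: simulate -> preprocess -> FCS -> group stats -> report.

One configuration object drives the run; every stochastic stage's seed,
every defaulted parameter and every output file lands in the run manifest,
so re-running from the same config reproduces deterministic outputs
bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fcs import (ConnectivityParams, FCSMap, aggregate_range,
                  compute_binned_fcs, smooth_map)
from .grid import MaskedVolumeGrid
from .io import (RunManifest, write_binned_maps, write_fcs_map, write_series,
                 write_table, write_volume)
from .neuropsych import cohort_summary
from .preproc import preprocess
from .stats import (ClusterCorrectionParams, estimate_smoothness,
                    extract_clusters, monte_carlo_cluster_threshold,
                    significant_voxel_count, voxelwise_ancova,
                    voxelwise_behaviour_regression)
from .synthetic import LINKED_DOMAIN, SimulationConfig, make_mask, simulate_cohort_table, simulate_subject_bold

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for a full synthetic-cohort analysis run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    cluster: ClusterCorrectionParams = field(default_factory=ClusterCorrectionParams)
    n_discard: int = 10
    band_hz: tuple[float, float] = (0.01, 0.1)
    smooth_fwhm_mm: float = 6.0
    behaviour_score: str = LINKED_DOMAIN
    global_signal_regression: bool = False
    write_subject_niftis: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discard < 0 or self.smooth_fwhm_mm < 0:
            raise PipelineError("n_discard and smooth_fwhm_mm must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def _tupled(d: dict) -> dict:
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        kwargs = dict(raw)
        try:
            if "simulation" in kwargs:
                kwargs["simulation"] = SimulationConfig(**_tupled(kwargs["simulation"]))
            if "connectivity" in kwargs:
                kwargs["connectivity"] = ConnectivityParams(**kwargs["connectivity"])
            if "cluster" in kwargs:
                kwargs["cluster"] = ClusterCorrectionParams(**_tupled(kwargs["cluster"]))
            if "band_hz" in kwargs:
                kwargs["band_hz"] = tuple(kwargs["band_hz"])
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise PipelineError(f"invalid pipeline configuration: {exc}") from exc


def _stage(manifest: RunManifest, name: str):
    manifest.parameters.setdefault("completed_stages", []).append(name)
    logger.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline and write all declared outputs.

    Returns a results dict with the cohort summary, cluster tables, per-bin
    significant-voxel counts and the manifest path. Stage failures abort
    with the stage name; the manifest records completed stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={"pipeline": _config_dict(config)},
        seeds={"cohort": config.simulation.seed, "monte_carlo": config.seed},
        software_version=__version__,
    )
    stage = "setup"
    try:
        sim = config.simulation
        grid = make_mask(sim)
        stage = "simulate"
        table = simulate_cohort_table(sim, grid)
        _stage(manifest, stage)

        stage = "preprocess+fcs"
        full_maps, binned_list = [], []
        short_maps, long_maps = [], []
        prep_log = None
        for idx in range(sim.n_subjects):
            series, _ = simulate_subject_bold(sim, sim.subject_group(idx), idx, grid)
            clean, prep_log = preprocess(
                series, n_discard=config.n_discard,
                low_hz=config.band_hz[0], high_hz=config.band_hz[1],
                include_global=config.global_signal_regression)
            binned = compute_binned_fcs(clean, grid, config.connectivity)
            full = FCSMap(binned.values.sum(axis=1), grid, config.connectivity)
            short, long = aggregate_range(binned)
            full_maps.append(smooth_map(full, config.smooth_fwhm_mm))
            short_maps.append(smooth_map(short, config.smooth_fwhm_mm))
            long_maps.append(smooth_map(long, config.smooth_fwhm_mm))
            binned_list.append(binned)
            if config.write_subject_niftis:
                sid = table.index[idx]
                write_series(out / f"{sid}_bold.nii.gz", series, grid)
                write_fcs_map(out / f"{sid}_fcs.nii.gz", full)
                write_binned_maps(out / f"{sid}_fcs_bins.nii.gz", binned)
        manifest.preprocessing_order = prep_log or []
        _stage(manifest, stage)

        stage = "cohort-summary"
        summary = cohort_summary(table)
        write_table(manifest.declare_output(
            "cohort_summary", out / "cohort_summary.tsv"), summary)
        write_table(manifest.declare_output(
            "subject_table", out / "subjects.tsv"), table.reset_index(drop=True))
        _stage(manifest, stage)

        stage = "group-stats"
        smap, resid = voxelwise_ancova(full_maps, table, grid,
                                       return_residuals=True)
        fwhm = estimate_smoothness(resid, grid)
        cluster = ClusterCorrectionParams(
            voxel_p=config.cluster.voxel_p, alpha=config.cluster.alpha,
            n_iterations=config.cluster.n_iterations,
            connectivity=config.cluster.connectivity,
            smoothness_fwhm_mm=tuple(fwhm))
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0]))
        extent = monte_carlo_cluster_threshold(grid, cluster, rng)
        clusters = extract_clusters(smap, cluster, extent)
        write_volume(manifest.declare_output(
            "group_tmap", out / "group_fcs_tmap.nii.gz"),
            grid.unmask(smap.values), grid.voxel_size_mm)
        write_table(manifest.declare_output(
            "group_clusters", out / "group_fcs_clusters.tsv"), clusters)
        manifest.parameters.update({
            "estimated_smoothness_fwhm_mm": list(map(float, fwhm)),
            "extent_threshold_voxels": extent.n_voxels,
            "extent_threshold_mm3": extent.volume_mm3,
        })
        _stage(manifest, stage)

        stage = "per-bin-stats"
        n_bins = config.connectivity.n_bins
        bin_counts = []
        mc_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        for k in range(n_bins):
            bmask = binned_list[0].bin_masks[:, k]
            if bmask.sum() < 10:
                bin_counts.append(0)
                continue
            maps_k = [smooth_map(b.bin_map(k), config.smooth_fwhm_mm)
                      for b in binned_list]
            smap_k = voxelwise_ancova(maps_k, table, grid, analysis_mask=bmask)
            sub = MaskedVolumeGrid(grid.unmask(bmask.astype(float)) > 0.5,
                                   grid.voxel_size_mm, name=f"bin-{k}")
            extent_k = monte_carlo_cluster_threshold(sub, cluster, mc_rng)
            bin_counts.append(significant_voxel_count(smap_k, cluster, extent_k))
        counts = pd.DataFrame({
            "bin": np.arange(1, n_bins + 1),
            "edge_low_mm": config.connectivity.bin_edges_mm[:-1],
            "edge_high_mm": config.connectivity.bin_edges_mm[1:],
            "n_significant_voxels": bin_counts,
        })
        write_table(manifest.declare_output(
            "bin_significant_counts", out / "bin_significant_counts.tsv"), counts)
        _plot_bin_counts(counts, manifest.declare_output(
            "bin_counts_png", out / "bin_significant_counts.png"))
        _stage(manifest, stage)

        stage = "behaviour-regression"
        patients = table["group"] == "patient"
        bmap = voxelwise_behaviour_regression(
            [m for m, p in zip(long_maps, patients) if p],
            table[patients], grid, config.behaviour_score)
        bclusters = extract_clusters(bmap, cluster, extent)
        write_volume(manifest.declare_output(
            "behaviour_tmap", out / "behaviour_long_fcs_tmap.nii.gz"),
            grid.unmask(bmap.values), grid.voxel_size_mm)
        write_table(manifest.declare_output(
            "behaviour_clusters", out / "behaviour_long_fcs_clusters.tsv"),
            bclusters)
        _stage(manifest, stage)
    except Exception as exc:
        manifest.parameters["failed_stage"] = stage
        manifest.write(out / "manifest.json")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = manifest.write(out / "manifest.json")
    return {
        "cohort_summary": summary,
        "group_clusters": clusters,
        "bin_counts": counts,
        "behaviour_clusters": bclusters,
        "extent_threshold_voxels": extent.n_voxels,
        "estimated_smoothness_fwhm_mm": [float(f) for f in fwhm],
        "manifest": manifest,
        "manifest_path": manifest_path,
    }


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def _plot_bin_counts(counts: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.bar(counts["edge_low_mm"] + 5.0, counts["n_significant_voxels"], width=8.0)
    ax.set_xlabel("distance bin (mm)")
    ax.set_ylabel("significant voxels")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
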