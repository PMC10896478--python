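"""Synthetic two-group BOLD cohorts with known hub and distance structure.

The generator plants a small set of connectivity hubs inside an ellipsoidal
grey-matter mask. Each hub emits a band-limited (0.01-0.1 Hz) latent signal;
the latent signals of a subject are correlated according to a hub-by-hub
latent coupling matrix, and every voxel's time course is a Gaussian-decaying
spatial mixture of the hub signals plus spatially smooth and white noise.
Patients differ from controls in exactly one respect: latent couplings
between hub pairs separated by more than the long-range cut (default
100 mm) are multiplied by ``long_range_attenuation`` — the generative
analogue of long-distance disconnection, with 1 meaning no group effect.

Per-subject heterogeneity comes from a coupling gain ~ N(1, sd) applied to
all off-diagonal couplings. The subject's *realized* mean inter-hub
Fisher-z coupling (computed from the simulated latent signals) is the
"hub connectivity summary" that generates one cognitive domain score, so
brain-behaviour recovery is testable against ground truth.

Randomness: every subject draws from substreams seeded by
``(cohort seed, subject index, stream)`` so cohorts are reproducible
subject-by-subject, and demographic draws never share random numbers with
voxel noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .fcs import GAUSSIAN_FWHM_TO_SIGMA
from .grid import MaskedVolumeGrid
from .preproc import BoldSeries, _design_bandpass

logger = logging.getLogger(__name__)

_STREAM_BOLD = 0
_STREAM_TABLE = 1

#: Group demographic distributions: (mean, sd) for normals, p for Bernoulli.
DEMOGRAPHICS = {
    "patient": {"age": (65.2, 10.1), "education": (11.0, 3.4), "p_male": 17 / 36},
    "control": {"age": (71.0, 8.0), "education": (12.3, 3.5), "p_male": 7 / 34},
}

#: Cognitive domains drawn as plain group normals (no brain link).
DOMAIN_NORMS = {
    "episodic_memory": {"patient": (-0.32, 0.74), "control": (0.34, 0.63)},
    "executive": {"patient": (-0.31, 0.70), "control": (0.33, 0.56)},
    "visuospatial": {"patient": (-0.07, 1.09), "control": (0.08, 0.56)},
    "mmse": {"patient": (26.4, 3.7), "control": (28.3, 1.6)},
}

#: The domain whose score is generated from hub connectivity.
LINKED_DOMAIN = "information_processing_speed"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated two-group cohort."""

    grid_shape: tuple[int, int, int] = (48, 40, 36)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 240
    repetition_time_s: float = 2.0
    n_patients: int = 32
    n_controls: int = 34
    hub_centers: tuple[tuple[int, int, int], ...] | None = None
    hub_radius_mm: float = 3.0
    coupling_decay_mm: float = 4.5
    hub_coupling: float = 0.7
    long_range_cut_mm: float = 100.0
    long_range_attenuation: float = 0.5
    noise_sd: float = 0.55
    noise_jitter_sd: float = 0.5
    noise_jitter_fwhm_mm: float = 12.0
    smooth_noise_fwhm_mm: float = 6.0
    smooth_noise_sd: float = 0.2
    global_noise_sd: float = 0.0
    subject_coupling_sd: float = 0.05
    cognition_effect: float = 1.0
    cognition_noise_sd: float = 0.3
    band_hz: tuple[float, float] = (0.01, 0.1)
    baseline: float = 1000.0
    drift_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise SimulationError("grid_shape must be 3 positive integers")
        if not 0.0 <= self.long_range_attenuation <= 1.0:
            raise SimulationError("long_range_attenuation must lie in [0, 1]")
        if not 0.0 <= self.hub_coupling < 1.0:
            raise SimulationError("hub_coupling must lie in [0, 1)")
        for name in ("voxel_size_mm", "repetition_time_s", "hub_radius_mm",
                     "coupling_decay_mm", "noise_sd"):
            if not getattr(self, name) > 0:
                raise SimulationError(f"{name} must be positive")
        if self.smooth_noise_fwhm_mm < 0:
            raise SimulationError("smooth_noise_fwhm_mm must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def subject_group(self, index: int) -> str:
        return "patient" if index < self.n_patients else "control"

    def resolved_hub_centers(self, grid: MaskedVolumeGrid) -> np.ndarray:
        """Configured hub centres, or four defaults along the longest axis."""
        if self.hub_centers is not None:
            centers = np.asarray(self.hub_centers, dtype=int)
        else:
            shape = np.array(self.grid_shape)
            long_ax = int(np.argmax(shape))
            mid = (shape - 1) / 2.0
            centers = []
            for frac in (0.12, 0.38, 0.62, 0.88):
                c = mid.copy()
                c[long_ax] = frac * (shape[long_ax] - 1)
                centers.append(np.round(c).astype(int))
            centers = np.array(centers)
        for c in centers:
            if not grid.contains(c):
                raise SimulationError(f"hub centre {tuple(c)} is outside the mask")
        return centers


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    hub_mask: np.ndarray                       # boolean volume
    hub_centers: np.ndarray                    # (H, 3) voxel indices
    coupling_control: np.ndarray               # (H, H) latent correlations
    coupling_patient: np.ndarray
    inter_hub_distance_mm: np.ndarray          # (H, H)
    subject_gain: float | None = None
    subject_coupling: np.ndarray | None = None
    hub_summary: float | None = None           # realized mean inter-hub Fisher z
    group: str | None = None


def make_mask(config: SimulationConfig) -> MaskedVolumeGrid:
    """Connected ellipsoidal mask inscribed in the grid (semi-axes 45% of
    each grid extent)."""
    shape = np.array(config.grid_shape)
    center = (shape - 1) / 2.0
    semi = np.maximum(0.45 * shape, 0.5)
    idx = np.indices(config.grid_shape, dtype=float)
    dist2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    mask = dist2 <= 1.0
    if not mask.any():
        raise SimulationError("configured ellipsoid produced an empty mask")
    return MaskedVolumeGrid(mask, config.voxel_size_mm, name="synthetic-ellipsoid")


def hub_mask(config: SimulationConfig, grid: MaskedVolumeGrid,
             centers: np.ndarray | None = None) -> np.ndarray:
    """Boolean volume marking voxels within hub_radius_mm of any hub centre."""
    centers = config.resolved_hub_centers(grid) if centers is None else centers
    idx = np.indices(grid.shape, dtype=float) * config.voxel_size_mm
    out = np.zeros(grid.shape, dtype=bool)
    for c in centers:
        d2 = sum((idx[a] - c[a] * config.voxel_size_mm) ** 2 for a in range(3))
        out |= d2 <= config.hub_radius_mm ** 2
    return out & grid.mask


def _coupling_matrices(config: SimulationConfig, grid: MaskedVolumeGrid
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    centers = config.resolved_hub_centers(grid)
    pos = centers.astype(float) * config.voxel_size_mm
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    h = len(centers)
    control = np.full((h, h), config.hub_coupling)
    np.fill_diagonal(control, 1.0)
    patient = control.copy()
    far = dist > config.long_range_cut_mm
    patient[far] *= config.long_range_attenuation
    np.fill_diagonal(patient, 1.0)
    return centers, dist, control, patient


def nearest_correlation(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped nearest-correlation repair (unit diagonal)."""
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    if w.min() >= eps:
        return mat
    level = logging.WARNING if w.min() < -0.2 else logging.DEBUG
    logger.log(level, "latent coupling matrix not positive definite "
               "(min eigenvalue %.3g); applying nearest-correlation repair",
               w.min())
    fixed = (v * np.maximum(w, eps)) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _subject_rng(config: SimulationConfig, subject_seed: int,
                 stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(subject_seed), stream]))


def _subject_coupling(config: SimulationConfig, base: np.ndarray,
                      rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Scale off-diagonal couplings by a per-subject gain ~ N(1, sd)."""
    off_max = base[~np.eye(len(base), dtype=bool)].max() if len(base) > 1 else 0.0
    g_hi = 0.98 / off_max if off_max > 0 else 2.0
    gain = float(np.clip(1.0 + config.subject_coupling_sd * rng.standard_normal(),
                         0.1, g_hi))
    mat = base * gain
    np.fill_diagonal(mat, 1.0)
    return nearest_correlation(mat), gain


def _band_limited_latents(config: SimulationConfig, n_series: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Unit-variance white noise filtered to the analysis band."""
    sos = _design_bandpass(*config.band_hz, config.repetition_time_s)
    white = rng.standard_normal((n_series, config.n_timepoints))
    lat = signal.sosfiltfilt(sos, white, axis=1)
    lat -= lat.mean(axis=1, keepdims=True)
    lat /= lat.std(axis=1, keepdims=True)
    return lat


def _realized_summary(latents: np.ndarray) -> float:
    """Mean Fisher-z of realized inter-hub latent correlations."""
    c = np.corrcoef(latents)
    iu = np.triu_indices_from(c, k=1)
    return float(np.arctanh(np.clip(c[iu], -0.999999, 0.999999)).mean())


def _subject_ground_truth(config: SimulationConfig, grid: MaskedVolumeGrid,
                          group: str, rng: np.random.Generator
                          ) -> tuple[GroundTruth, np.ndarray]:
    """Draw (gain, latent signals) and assemble the subject ground truth."""
    centers, dist, control, patient = _coupling_matrices(config, grid)
    base = patient if group == "patient" else control
    coupling, gain = _subject_coupling(config, base, rng)
    iid = _band_limited_latents(config, len(centers), rng)
    chol = np.linalg.cholesky(nearest_correlation(coupling))
    latents = chol @ iid
    gt = GroundTruth(
        hub_mask=hub_mask(config, grid, centers),
        hub_centers=centers,
        coupling_control=control,
        coupling_patient=patient,
        inter_hub_distance_mm=dist,
        subject_gain=gain,
        subject_coupling=coupling,
        hub_summary=_realized_summary(latents),
        group=group,
    )
    return gt, latents


def _smooth_noise(config: SimulationConfig, grid: MaskedVolumeGrid,
                  rng: np.random.Generator) -> np.ndarray:
    """Spatially smooth unit-variance noise, (n_voxels, T)."""
    sigma = (config.smooth_noise_fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA
             / config.voxel_size_mm)
    if sigma == 0:
        return rng.standard_normal((grid.n_voxels, config.n_timepoints))
    impulse = np.zeros(grid.shape)
    impulse[tuple(s // 2 for s in grid.shape)] = 1.0
    scale = np.sqrt((ndimage.gaussian_filter(impulse, sigma) ** 2).sum())
    out = np.empty((grid.n_voxels, config.n_timepoints))
    for t in range(config.n_timepoints):
        vol = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma)
        out[:, t] = vol[grid.mask] / scale
    return out


def simulate_subject_bold(config: SimulationConfig, group: str,
                          subject_seed: int,
                          grid: MaskedVolumeGrid | None = None
                          ) -> tuple[BoldSeries, GroundTruth]:
    """One subject's masked 4D series plus the generating ground truth.

    ``subject_seed`` is the subject's index within the cohort; the actual
    random stream is derived from (cohort seed, subject_seed), so the same
    pair is bit-reproducible.
    """
    if group not in ("patient", "control"):
        raise SimulationError(f"unknown group {group!r}")
    if config.n_timepoints < 50:
        raise SimulationError("n_timepoints must be at least 50")
    grid = grid or make_mask(config)
    if grid.n_voxels < 2:
        raise SimulationError("mask is degenerate (needs >= 2 voxels for FCS)")
    rng = _subject_rng(config, subject_seed, _STREAM_BOLD)
    gt, latents = _subject_ground_truth(config, grid, group, rng)

    pos = gt.hub_centers.astype(float) * config.voxel_size_mm
    d = np.linalg.norm(grid.voxel_coordinates_mm[:, None, :] - pos[None, :, :],
                       axis=-1)
    loadings = np.exp(-d ** 2 / (2.0 * config.coupling_decay_mm ** 2))
    loadings[loadings < 0.01] = 0.0      # truncated for sparsity

    data = loadings @ latents
    if config.global_noise_sd > 0:
        # A spatially uniform, band-limited nuisance fluctuation: the
        # component that global-signal regression is meant to remove.
        data = data + config.global_noise_sd * _band_limited_latents(config, 1, rng)
    data += config.smooth_noise_sd * _smooth_noise(config, grid, rng)
    # Regional noise-level heterogeneity (tSNR variability): a per-subject
    # spatially smooth log-normal field scales the white-noise sd, so voxel
    # correlations fluctuate subject-to-subject at a scale the map
    # smoothing does not average away.
    jit = np.ones(grid.n_voxels)
    if config.noise_jitter_sd > 0:
        sig = (config.noise_jitter_fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA
               / config.voxel_size_mm)
        field = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sig)
        field = field[grid.mask]
        field /= field.std() or 1.0
        jit = np.exp(config.noise_jitter_sd * field
                     - config.noise_jitter_sd ** 2 / 2.0)
    data += (config.noise_sd * jit)[:, None] * rng.standard_normal(data.shape)
    ramp = np.linspace(-1.0, 1.0, config.n_timepoints)
    data += config.drift_sd * rng.standard_normal((grid.n_voxels, 1)) * ramp
    data += config.baseline
    series = BoldSeries(data, config.repetition_time_s, mask_ref=grid.name)
    return series, gt


def _cohort_summaries(config: SimulationConfig, grid: MaskedVolumeGrid
                      ) -> list[GroundTruth]:
    out = []
    for idx in range(config.n_subjects):
        rng = _subject_rng(config, idx, _STREAM_BOLD)
        gt, _ = _subject_ground_truth(config, grid, config.subject_group(idx), rng)
        out.append(gt)
    return out


def simulate_cohort_table(config: SimulationConfig,
                          grid: MaskedVolumeGrid | None = None) -> pd.DataFrame:
    """Subject table: group, demographics and cognitive domain scores.

    Demographics follow the group normal/Bernoulli defaults; the linked
    domain score is ``cognition_effect`` times the cohort-standardized
    realized hub-connectivity summary plus independent noise, so patients
    (attenuated long-range coupling) score lower whenever attenuation < 1.
    """
    if config.n_patients < 2 or config.n_controls < 2:
        raise SimulationError("need at least 2 subjects per group")
    grid = grid or make_mask(config)
    truths = _cohort_summaries(config, grid)
    summaries = np.array([gt.hub_summary for gt in truths])
    sd = summaries.std()
    standardized = (summaries - summaries.mean()) / (sd if sd > 0 else 1.0)
    rows = []
    for idx in range(config.n_subjects):
        group = config.subject_group(idx)
        rng = _subject_rng(config, idx, _STREAM_TABLE)
        demo = DEMOGRAPHICS[group]
        row = {
            "subject": f"sub-{idx:03d}",
            "group": group,
            "age": float(rng.normal(*demo["age"])),
            "sex": int(rng.random() < demo["p_male"]),
            "education": float(max(rng.normal(*demo["education"]), 0.0)),
        }
        for dom, norms in DOMAIN_NORMS.items():
            row[dom] = float(rng.normal(*norms[group]))
        row["mmse"] = float(np.clip(round(row["mmse"]), 0, 30))
        row[LINKED_DOMAIN] = float(
            config.cognition_effect * standardized[idx]
            + config.cognition_noise_sd * rng.standard_normal())
        row["hub_summary"] = float(summaries[idx])
        row["coupling_gain"] = float(truths[idx].subject_gain)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject", drop=False)


def iter_cohort_bold(config: SimulationConfig,
                     grid: MaskedVolumeGrid | None = None):
    """Yield (index, group, BoldSeries, GroundTruth) for every subject."""
    grid = grid or make_mask(config)
    for idx in range(config.n_subjects):
        series, gt = simulate_subject_bold(config, config.subject_group(idx),
                                           idx, grid)
        yield idx, config.subject_group(idx), series, gt
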