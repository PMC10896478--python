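"""Temporal preprocessing of masked BOLD time series.

The stages here mirror the standard resting-state pipeline once spatial
preprocessing (realignment, normalization to a common space) is done:
discard of initial volumes for scanner stabilization, band-pass filtering
to the low-frequency BOLD band, linear detrending, and nuisance regression
(motion parameters, global / CSF / white-matter signals). The executed
order of stages is recorded so every run is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)


class PreprocError(ValueError):
    pass


@dataclass
class BoldSeries:
    """Masked-voxel x timepoint matrix at a fixed repetition time.

    ``data`` has one row per in-mask voxel and one column per volume; units
    are arbitrary BOLD-like intensities. ``mask_ref`` names the grid the
    rows were sampled on.
    """

    data: np.ndarray
    repetition_time_s: float = 2.0
    mask_ref: str = "grid"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise PreprocError(f"series data must be 2D, got {data.ndim}D")
        if data.shape[1] < 2:
            raise PreprocError("series needs at least 2 timepoints")
        if not np.all(np.isfinite(data)):
            raise PreprocError("series contains non-finite values")
        if not self.repetition_time_s > 0:
            raise PreprocError("repetition_time_s must be positive")
        self.data = data

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class NuisanceSet:
    """Timepoint x regressor matrix with column labels.

    Typical columns: six rigid-body motion parameters, mean global signal,
    CSF signal, white-matter signal. For synthetic cohorts without motion,
    zero-filled motion columns are accepted and silently dropped at fit
    time (they carry no information beyond the intercept); the drop is
    logged.
    """

    regressors: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        reg = np.asarray(self.regressors, dtype=float)
        if reg.size == 0:
            reg = reg.reshape(reg.shape[0] if reg.ndim else 0, 0)
        if reg.ndim != 2:
            raise PreprocError("regressors must be a 2D timepoint x regressor matrix")
        if not self.labels:
            self.labels = [f"nuisance_{k}" for k in range(reg.shape[1])]
        if len(self.labels) != reg.shape[1]:
            raise PreprocError("labels must match regressor columns")
        self.regressors = reg

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.regressors.shape[1]


def global_signal(series: BoldSeries) -> np.ndarray:
    """Mean masked time course, the global-signal nuisance regressor."""
    return series.data.mean(axis=0)


def discard_initial_volumes(series: BoldSeries, n_discard: int = 10) -> BoldSeries:
    """Drop the first ``n_discard`` volumes (participant acclimatization)."""
    if n_discard < 0:
        raise PreprocError("n_discard must be nonnegative")
    if n_discard >= series.n_timepoints:
        raise PreprocError(
            f"cannot discard {n_discard} of {series.n_timepoints} timepoints"
        )
    return replace(series, data=series.data[:, n_discard:].copy())


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Remove the per-voxel OLS fit on (intercept, time).

    Residuals are exactly orthogonal to a linear ramp; a pure ramp input is
    annihilated to numerical zero.
    """
    if series.n_timepoints < 3:
        raise PreprocError("detrending needs at least 3 timepoints")
    t = np.arange(series.n_timepoints, dtype=float)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, series.data.T, rcond=None)
    return replace(series, data=series.data - (X @ beta).T)


def _design_bandpass(low_hz: float, high_hz: float, repetition_time_s: float,
                     order: int = 2) -> np.ndarray:
    fs = 1.0 / repetition_time_s
    nyquist = fs / 2.0
    if not 0 < low_hz < high_hz:
        raise PreprocError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise PreprocError(
            f"high_hz {high_hz} must be below the Nyquist frequency {nyquist}"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                         output="sos")


def bandpass_filter(series: BoldSeries, low_hz: float = 0.01,
                    high_hz: float = 0.1, order: int = 2) -> BoldSeries:
    """Zero-phase Butterworth band-pass, default 0.01-0.1 Hz.

    Applied forward-backward (``sosfiltfilt``) so no phase lag is introduced
    into the correlation structure; the effective magnitude response is the
    squared Butterworth response of the stated order.
    """
    sos = _design_bandpass(low_hz, high_hz, series.repetition_time_s, order)
    return replace(series, data=signal.sosfiltfilt(sos, series.data, axis=1))


def _check_full_rank(X: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [labels[k] for k in np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))]
        raise PreprocError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'unidentified'}"
        )


def regress_nuisance(series: BoldSeries, nuisance: NuisanceSet,
                     include_trend: bool = False) -> BoldSeries:
    """Per-voxel OLS residuals after regressing on intercept + nuisance set.

    Constant (e.g. zero-filled placeholder motion) columns are dropped with
    a log message since the intercept already spans them. With
    ``include_trend`` a linear ramp column is folded into the same design,
    combining detrending and nuisance removal in one projection.
    """
    reg = nuisance.regressors
    if reg.shape[0] and reg.shape[0] != series.n_timepoints:
        raise PreprocError(
            f"nuisance rows ({reg.shape[0]}) != series timepoints "
            f"({series.n_timepoints})"
        )
    keep, labels = [], []
    for k in range(reg.shape[1]):
        if np.ptp(reg[:, k]) == 0.0:
            logger.info("dropping constant nuisance column %r", nuisance.labels[k])
            continue
        keep.append(reg[:, k])
        labels.append(nuisance.labels[k])
    t = np.arange(series.n_timepoints, dtype=float)
    cols = [np.ones_like(t)] + ([t] if include_trend else []) + keep
    labels = ["intercept"] + (["trend"] if include_trend else []) + labels
    X = np.column_stack(cols)
    _check_full_rank(X, labels)
    beta, *_ = np.linalg.lstsq(X, series.data.T, rcond=None)
    return replace(series, data=series.data - (X @ beta).T)


def preprocess(series: BoldSeries, nuisance: NuisanceSet | None = None,
               n_discard: int = 10, low_hz: float = 0.01, high_hz: float = 0.1,
               detrend: bool = True,
               include_global: bool = False) -> tuple[BoldSeries, list[str]]:
    """Run the standard temporal pipeline; returns (series, executed stages).

    Order: discard initial volumes -> band-pass -> combined linear
    detrend + nuisance regression. With ``include_global`` the mean masked
    time course of the filtered data is appended as a nuisance regressor.
    Any externally supplied nuisance rows must match the post-discard
    timepoint count.
    """
    log: list[str] = []
    if n_discard:
        series = discard_initial_volumes(series, n_discard)
        log.append(f"discard_initial_volumes(n={n_discard})")
    series = bandpass_filter(series, low_hz, high_hz)
    log.append(f"bandpass_filter({low_hz}-{high_hz} Hz)")
    if nuisance is None:
        nuisance = NuisanceSet(np.empty((series.n_timepoints, 0)))
    if include_global:
        nuisance = NuisanceSet(
            np.column_stack([nuisance.regressors, global_signal(series)])
            if nuisance.n_regressors else global_signal(series)[:, None],
            nuisance.labels + ["global"])
    series = regress_nuisance(series, nuisance, include_trend=detrend)
    log.append(
        "regress_nuisance(" + ",".join(nuisance.labels or ["intercept-only"]) +
        (";trend" if detrend else "") + ")"
    )
    logger.info("preprocessing order: %s", " -> ".join(log))
    return series, log
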