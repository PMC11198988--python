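"""Denoising of extracted region time series and epoch splitting.

Denoising regresses out nuisance confounds jointly with a discrete-cosine
high-pass basis (128 s cutoff by default), applies a zero-phase Butterworth
low-pass (100 s cutoff, order 5), and z-scores each region. Task scans are
spliced into three equal-length epochs of 210 volumes — baseline, early
learning, late learning — after discarding leading buffer volumes, with the
late epoch anchored to the end of the learning scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .io import RegionTimeSeries, ValidationError


@dataclass
class ConfoundSet:
    """Volume-by-regressor nuisance matrix (motion, physiological, etc.)."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[1] != len(self.names):
            raise ValidationError("confound names do not match columns")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]


@dataclass
class EpochSpec:
    """Epoch layout: leading volumes to discard and epoch length in volumes."""

    discard_leading: int = 6
    epoch_length: int = 210

    def __post_init__(self) -> None:
        if self.discard_leading < 0 or self.epoch_length <= 0:
            raise ValidationError("epoch spec fields must be positive")


def dct_basis(n_volumes: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass basis: cosines with period longer than ``cutoff_s``.

    Column k is cos(pi * k * (2n + 1) / (2N)); the number of columns is
    floor(2 * N * tr / cutoff_s), the standard drift basis.
    """
    if cutoff_s <= 2 * tr:
        raise ValidationError(f"cutoff {cutoff_s}s incompatible with tr={tr}s")
    n_basis = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    n = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_volumes)) for k in range(1, n_basis + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase the rank, in order
        collinear = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                collinear.append(names[j])
            r = rj
        raise ValidationError(f"design is rank-deficient; collinear regressors: {collinear}")


def denoise(
    ts: RegionTimeSeries,
    confounds: ConfoundSet | None = None,
    highpass_s: float = 128.0,
    lowpass_s: float = 100.0,
    butter_order: int = 5,
) -> RegionTimeSeries:
    """Confound + cosine-drift regression, Butterworth low-pass, z-score.

    The confounds and the discrete-cosine basis are removed in one joint
    ordinary-least-squares projection (so neither step reintroduces variance
    removed by the other), then each region is low-pass filtered
    forward-backward (zero phase) and z-scored to mean 0, variance 1.
    """
    T = ts.n_volumes
    tr = ts.tr
    for cutoff in (highpass_s, lowpass_s):
        if cutoff <= 2 * tr:
            raise ValidationError(f"cutoff {cutoff}s incompatible with tr={tr}s (need > 2*tr)")
    if 2.0 * lowpass_s > highpass_s:
        warnings.warn(
            f"narrow passband: high-pass {1.0 / highpass_s:.4g} Hz and low-pass "
            f"{1.0 / lowpass_s:.4g} Hz leave little signal; cutoffs applied as configured"
        )
    if confounds is not None and confounds.n_volumes != T:
        raise ValidationError(
            f"confounds have {confounds.n_volumes} rows for {T} volumes"
        )

    drift = dct_basis(T, tr, highpass_s)
    parts = [np.ones((T, 1)), drift]
    names = ["intercept"] + [f"dct_{k}" for k in range(1, drift.shape[1] + 1)]
    if confounds is not None and confounds.values.shape[1] > 0:
        parts.append(confounds.values)
        names += list(confounds.names)
    X = np.hstack(parts)
    _check_rank(X, names)
    # OLS residuals, all regions at once
    beta, *_ = np.linalg.lstsq(X, ts.values.T, rcond=None)
    resid = ts.values.T - X @ beta  # volumes x regions

    nyq = 0.5 / tr
    b, a = butter(butter_order, (1.0 / lowpass_s) / nyq, btype="low")
    filtered = filtfilt(b, a, resid, axis=0)

    mu = filtered.mean(axis=0)
    sd = filtered.std(axis=0)
    if np.any(sd == 0):
        bad = ts.region_ids[int(np.argmin(sd))]
        raise ValidationError(f"region {bad!r} is constant after filtering")
    z = (filtered - mu) / sd
    return RegionTimeSeries(values=z.T, region_ids=ts.region_ids, tr=tr)


def split_epochs(
    baseline_ts: RegionTimeSeries,
    learning_ts: RegionTimeSeries,
    spec: EpochSpec = EpochSpec(),
) -> tuple[RegionTimeSeries, RegionTimeSeries, RegionTimeSeries]:
    """Cut the baseline and learning scans into three equal task epochs.

    Baseline and early learning take volumes [discard, discard + L); the late
    epoch is the final L volumes before the trailing ``discard`` buffer of the
    learning scan, mirroring the first/last-70-trials design (a mid-scan gap
    is allowed).
    """
    d, L = spec.discard_leading, spec.epoch_length
    if baseline_ts.n_volumes < d + L:
        raise ValidationError(
            f"baseline scan has {baseline_ts.n_volumes} volumes; needs >= {d + L}"
        )
    if learning_ts.n_volumes < d + 2 * L:
        raise ValidationError(
            f"learning scan has {learning_ts.n_volumes} volumes; needs >= {d + 2 * L}"
        )

    def cut(ts: RegionTimeSeries, start: int) -> RegionTimeSeries:
        return RegionTimeSeries(
            values=ts.values[:, start : start + L], region_ids=ts.region_ids, tr=ts.tr
        )

    baseline = cut(baseline_ts, d)
    early = cut(learning_ts, d)
    late_start = learning_ts.n_volumes - d - L
    if late_start < d + L:
        warnings.warn("late epoch overlaps the early epoch (short learning scan)")
    late = cut(learning_ts, late_start)
    return baseline, early, late
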