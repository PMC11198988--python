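"""Reward-based motor task: geometry, scoring, trial processing, learning scores.

Participants trace a subtly curved "visible" path (half-cycle sine, amplitude
0.15 x target distance) from a start position to a target 60 mm away, but are
covertly rewarded for tracing its mirror image (the "reward" path). The score
on a trial compares the traced x positions, interpolated at six fixed y
offsets, against the reward path, normalized by the error of a reference sine
of amplitude 0.5 x target distance:

    score = 100 * (1 - E / N),   clipped to [0, 100]

where E = sum_y |x(y) - x_reward(y)| and N = sum_y |0.5 D sin(pi y / D)|.
Under this scaling a perfectly traced visible path scores exactly 40 points
and a straight line up the midline scores 70.

Learning curves (trial scores averaged over 8-trial bins) are summarized by
functional PCA of spline-smoothed curves; each subject's loading on the
dominant component is their "learning score".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import ValidationError


class TrialTimeoutError(ValueError):
    """The trajectory never reached the target distance."""


# ---------------------------------------------------------------------------
# geometry and trial containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskGeometry:
    """Task geometry in millimetres; origin at the start position, +y toward target."""

    target_distance: float = 60.0
    visible_amplitude: float | None = None  # default 0.15 * D; sign = visible side
    reference_amplitude: float | None = None  # default 0.5 * D
    time_limit: float = 4.5  # seconds
    sentinel: tuple[float, float] = (-150.0, 150.0)  # cursor-jump default position

    def __post_init__(self) -> None:
        if self.target_distance <= 0:
            raise ValidationError("target_distance must be positive")
        if self.visible_amplitude is None:
            object.__setattr__(self, "visible_amplitude", 0.15 * self.target_distance)
        if self.reference_amplitude is None:
            object.__setattr__(self, "reference_amplitude", 0.5 * self.target_distance)

    @property
    def score_ys(self) -> np.ndarray:
        """The six scoring offsets: each cm of y displacement up to the target."""
        return self.target_distance / 6.0 * np.arange(1, 7)

    def visible_x(self, y) -> np.ndarray:
        return self.visible_amplitude * np.sin(np.pi * np.asarray(y) / self.target_distance)

    def reward_x(self, y) -> np.ndarray:
        """The rewarded path: mirror image of the visible path across x = 0."""
        return -self.visible_x(y)

    def mirrored(self) -> "TaskGeometry":
        return replace(self, visible_amplitude=-self.visible_amplitude)


@dataclass
class Trajectory:
    """Ordered (t, x, y) fingertip samples for one trial."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    trial: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(f"trial {self.trial}: timestamps not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError(f"trial {self.trial}: non-finite coordinates")


FLAG_KEPT = "kept"
FLAG_TIMEOUT = "timeout"
FLAG_CURSOR_JUMP = "cursor_jump"
FLAG_SLOW = "slow_outlier"


@dataclass
class TrialSet:
    """Trajectories with per-trial scores, kinematics and exclusion flags."""

    trajectories: list[Trajectory]
    scores: np.ndarray | None = None
    rt: np.ndarray | None = None
    mt: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.flags:
            self.flags = [FLAG_KEPT] * len(self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def kept(self) -> np.ndarray:
        return np.array([f == FLAG_KEPT for f in self.flags])


@dataclass
class LearningCurve:
    """Mean score per 8-trial bin for one subject."""

    values: np.ndarray
    subject: str
    bin_width: int = 8

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if np.any((v < 0) | (v > 100)):
            raise ValidationError("binned scores must lie in [0, 100]")
        self.values = v


@dataclass
class LearningScore:
    """Subject loading on the dominant functional component of the curves."""

    subject: str
    score: float
    variance_explained: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.variance_explained <= 1.0:
            raise ValidationError("variance_explained must be in [0, 1]")


# ---------------------------------------------------------------------------
# scoring and kinematics
# ---------------------------------------------------------------------------


def first_crossing(traj: Trajectory, level: float) -> tuple[float, float] | None:
    """Time and x position of the first upward crossing of y = level.

    Linear interpolation between the bracketing samples; None if the
    trajectory never reaches the level.
    """
    y = traj.y
    if y[0] >= level:
        return float(traj.t[0]), float(traj.x[0])
    above = np.flatnonzero((y[1:] >= level) & (y[:-1] < level))
    if above.size == 0:
        return None
    i = int(above[0])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    t = traj.t[i] + frac * (traj.t[i + 1] - traj.t[i])
    x = traj.x[i] + frac * (traj.x[i + 1] - traj.x[i])
    return float(t), float(x)


def score_trajectory(traj: Trajectory, geom: TaskGeometry = TaskGeometry()) -> float:
    """Reward score in [0, 100] for one trajectory.

    x is read off at the first upward crossing of each scoring y offset; the
    summed absolute deviation from the reward path is normalized by the
    reference-sine deviation and converted to 100 * (1 - E/N).
    """
    D = geom.target_distance
    xs = []
    for yk in geom.score_ys:
        hit = first_crossing(traj, yk)
        if hit is None:
            raise TrialTimeoutError(
                f"trial {traj.trial}: trajectory never reaches y = {yk:g} mm"
            )
        xs.append(hit[1])
    xs = np.array(xs)
    E = float(np.sum(np.abs(xs - geom.reward_x(geom.score_ys))))
    N = float(
        np.sum(np.abs(geom.reference_amplitude * np.sin(np.pi * geom.score_ys / D)))
    )
    return float(np.clip(100.0 * (1.0 - E / N), 0.0, 100.0))


def trial_kinematics(traj: Trajectory, geom: TaskGeometry = TaskGeometry()) -> tuple[float, float]:
    """Reaction time (onset to 10% of target distance) and movement time (to target)."""
    D = geom.target_distance
    start = first_crossing(traj, 0.1 * D)
    if start is None:
        raise TrialTimeoutError(f"trial {traj.trial}: never crosses 10% of the distance")
    end = first_crossing(traj, D)
    if end is None:
        raise TrialTimeoutError(f"trial {traj.trial}: never reaches the target distance")
    rt = start[0] - traj.t[0]
    mt = end[0] - start[0]
    return float(rt), float(mt)


def compute_scores(trial_set: TrialSet, geom: TaskGeometry = TaskGeometry()) -> TrialSet:
    """Populate scores, RT and MT, flagging trials that never reach the target."""
    n = len(trial_set)
    scores = np.full(n, np.nan)
    rt = np.full(n, np.nan)
    mt = np.full(n, np.nan)
    flags = list(trial_set.flags)
    for i, traj in enumerate(trial_set.trajectories):
        try:
            rt[i], mt[i] = trial_kinematics(traj, geom)
            scores[i] = score_trajectory(traj, geom)
        except TrialTimeoutError:
            flags[i] = FLAG_TIMEOUT
    return TrialSet(trajectories=trial_set.trajectories, scores=scores, rt=rt, mt=mt, flags=flags)


def filter_trials(
    trial_set: TrialSet,
    geom: TaskGeometry = TaskGeometry(),
    slow_fraction: float = 0.0005,
) -> TrialSet:
    """Flag excluded trials; all trials are retained with their reason.

    Exclusions: (1) timeouts — no arrival at the target within the time
    limit; (2) cursor jumps — any pre-arrival sample at the sentinel
    position (the device default when fingertip pressure is lost); (3) the
    slowest ``slow_fraction`` of trials by MT and, separately, by RT across
    the pooled set (ceil count; no lower trim).
    """
    ts = trial_set
    if ts.scores is None:
        ts = compute_scores(ts, geom)
    flags = list(ts.flags)
    D = geom.target_distance
    sx, sy = geom.sentinel
    for i, traj in enumerate(ts.trajectories):
        if flags[i] != FLAG_KEPT:
            continue
        # sentinel samples (device dropout) cannot count toward arrival
        jump = np.isclose(traj.x, sx, atol=1e-9) & np.isclose(traj.y, sy, atol=1e-9)
        clean = traj
        if jump.any():
            keep = ~jump
            if keep.sum() < 2:
                flags[i] = FLAG_CURSOR_JUMP
                continue
            clean = Trajectory(t=traj.t[keep], x=traj.x[keep], y=traj.y[keep], trial=traj.trial)
        arrival = first_crossing(clean, D)
        if jump.any() and (arrival is None or traj.t[jump][0] < arrival[0]):
            flags[i] = FLAG_CURSOR_JUMP
            continue
        # timeout: arrival later than the limit still counts as no arrival
        if arrival is None or arrival[0] - traj.t[0] > geom.time_limit:
            flags[i] = FLAG_TIMEOUT
    # pooled slow-trial trim on MT and RT among still-kept trials
    kept_idx = np.flatnonzero([f == FLAG_KEPT for f in flags])
    if kept_idx.size:
        n_trim = math.ceil(slow_fraction * kept_idx.size)
        for values in (ts.mt, ts.rt):
            order = kept_idx[np.argsort(-values[kept_idx], kind="stable")]
            for i in order[:n_trim]:
                flags[i] = FLAG_SLOW
    return TrialSet(trajectories=ts.trajectories, scores=ts.scores, rt=ts.rt, mt=ts.mt, flags=flags)


# ---------------------------------------------------------------------------
# path variability
# ---------------------------------------------------------------------------


def resample_paths(trial_set: TrialSet, geom: TaskGeometry = TaskGeometry(), k: int = 10) -> np.ndarray:
    """x positions at k equally spaced y offsets (D/k, 2D/k, ..., D) per trial."""
    D = geom.target_distance
    ys = D / k * np.arange(1, k + 1)
    X = np.empty((len(trial_set), k))
    for i, traj in enumerate(trial_set.trajectories):
        for j, yk in enumerate(ys):
            hit = first_crossing(traj, yk)
            if hit is None:
                raise TrialTimeoutError(f"trial {traj.trial}: cannot resample to y = {yk:g}")
            X[i, j] = hit[1]
    return X


def path_variability(
    trial_set: TrialSet, geom: TaskGeometry = TaskGeometry(), half_window: int = 3, k: int = 10
) -> np.ndarray:
    """Per-trial mean |x - sliding-window-average x| over the k resampled points.

    The average path at trial t is the mean of trials [t - 3, t + 3]
    (seven-trial window, truncated at the ends).
    """
    if len(trial_set) < 1:
        raise ValidationError("need at least one trial")
    X = resample_paths(trial_set, geom, k)
    n = X.shape[0]
    out = np.empty(n)
    for t in range(n):
        lo, hi = max(0, t - half_window), min(n, t + half_window + 1)
        out[t] = np.mean(np.abs(X[t] - X[lo:hi].mean(axis=0)))
    return out


# ---------------------------------------------------------------------------
# learning curves and functional PCA
# ---------------------------------------------------------------------------


def bin_scores(scores: np.ndarray, kept: np.ndarray | None = None, bin_width: int = 8) -> np.ndarray:
    """Mean score per consecutive bin of ``bin_width`` trials, skipping excluded trials."""
    scores = np.asarray(scores, float)
    n = len(scores)
    if kept is None:
        kept = np.isfinite(scores)
    else:
        kept = np.asarray(kept, bool) & np.isfinite(scores)
    n_bins = n // bin_width
    out = np.empty(n_bins)
    for b in range(n_bins):
        sl = slice(b * bin_width, (b + 1) * bin_width)
        vals = scores[sl][kept[sl]]
        out[b] = vals.mean() if vals.size else np.nan
    if np.any(np.isnan(out)):
        raise ValidationError("a bin has no kept trials; cannot form a learning curve")
    return out


def _spline_basis(x: np.ndarray, n_eval: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cubic B-spline basis with knots at the bin centers.

    Returns the design matrix at ``x``, the design matrix at ``n_eval`` and
    the roughness penalty matrix (integrated squared second derivative,
    computed exactly with Gauss-Legendre quadrature on each knot interval).
    """
    from scipy.interpolate import BSpline

    interior = x[1:-1]
    t = np.concatenate([[x[0]] * 4, interior, [x[-1]] * 4])
    n_basis = len(t) - 4

    def design(pts: np.ndarray, nu: int = 0) -> np.ndarray:
        cols = []
        for j in range(n_basis):
            c = np.zeros(n_basis)
            c[j] = 1.0
            sp = BSpline(t, c, 3)
            if nu:
                sp = sp.derivative(nu)
            cols.append(sp(pts))
        return np.column_stack(cols)

    B = design(x)
    B_eval = design(n_eval)
    # 3-point Gauss-Legendre per interval: exact for the piecewise-quadratic
    # integrand formed by products of piecewise-linear second derivatives
    nodes, weights = np.polynomial.legendre.leggauss(3)
    breaks = np.unique(t)
    qx, qw = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        qx.append((b - a) / 2 * nodes + (a + b) / 2)
        qw.append((b - a) / 2 * weights)
    qx = np.concatenate(qx)
    qw = np.concatenate(qw)
    D2 = design(qx, nu=2)
    R = (D2 * qw[:, None]).T @ D2
    return B, B_eval, R


def learning_scores(
    curves: list[LearningCurve],
    n_grid: int = 101,
    lambda_grid: np.ndarray | None = None,
) -> tuple[list[LearningScore], dict]:
    """Functional PCA of spline-smoothed learning curves.

    Each curve is smoothed with a cubic spline basis (knots at bin centers)
    under a roughness penalty whose weight is chosen by generalized
    cross-validation (one shared penalty, minimizing the mean GCV score).
    Smoothed curves are evaluated on a fine grid and decomposed by a
    quadrature-weighted eigendecomposition of their covariance; the top
    component's per-subject score is returned, with its sign oriented so
    that a positive score goes with higher final-quarter performance.

    Returns the per-subject scores and a diagnostics dict (chosen penalty,
    mean curve, top eigenfunction, grid).
    """
    if len(curves) < 3:
        raise ValidationError("need at least 3 subjects for functional PCA")
    n_bins = len(curves[0].values)
    if any(len(c.values) != n_bins for c in curves):
        raise ValidationError("all curves must have the same number of bins")
    Y = np.array([c.values for c in curves])  # subjects x bins
    if np.allclose(Y, Y[0], atol=1e-12):
        raise ValidationError("curves are identical; no variability to decompose")

    x = np.arange(1, n_bins + 1, dtype=float)  # bin centers in bin units
    grid = np.linspace(x[0], x[-1], n_grid)
    B, B_eval, R = _spline_basis(x, grid)
    if lambda_grid is None:
        lambda_grid = np.logspace(-6, 4, 41)

    BtB = B.T @ B
    n = n_bins
    best = (np.inf, None)
    for lam in lambda_grid:
        A = np.linalg.solve(BtB + lam * R, B.T)
        H = B @ A
        df = float(np.trace(H))
        resid = Y - Y @ H.T
        gcv = np.mean(n * np.sum(resid**2, axis=1) / (n - df) ** 2)
        if gcv < best[0]:
            best = (gcv, lam)
    lam = best[1]
    coef = np.linalg.solve(BtB + lam * R, B.T @ Y.T)  # basis x subjects
    smooth = (B_eval @ coef).T  # subjects x grid

    mean_curve = smooth.mean(axis=0)
    Xc = smooth - mean_curve
    # trapezoid quadrature weights for the L2 inner product on the grid
    w = np.gradient(grid)
    Mw = Xc * np.sqrt(w)
    U, s, Vt = np.linalg.svd(Mw, full_matrices=False)
    total = float(np.sum(s**2))
    ve = float(s[0] ** 2 / total)
    phi = Vt[0] / np.sqrt(w)
    scores = Xc @ (w * phi)
    # orientation: positive learning score = better late performance
    late = Y[:, -max(1, n_bins // 4):].mean(axis=1)
    if np.corrcoef(scores, late)[0, 1] < 0:
        scores = -scores
        phi = -phi
    results = [
        LearningScore(subject=c.subject, score=float(scores[i]), variance_explained=ve)
        for i, c in enumerate(curves)
    ]
    diag = {"penalty": float(lam), "mean_curve": mean_curve, "eigenfunction": phi, "grid": grid}
    return results, diag


# ---------------------------------------------------------------------------
# trajectory-level learner simulator
# ---------------------------------------------------------------------------


def simulate_learner(
    geom: TaskGeometry = TaskGeometry(),
    aptitude: float = 0.5,
    exploration_sd: float = 2.0,
    n_trials: int = 200,
    seed: int = 0,
    execution_noise: float = 0.5,
    n_samples: int = 100,
    trial_duration: float = 1.0,
) -> TrialSet:
    """Simulate a reward-following learner producing full fingertip trajectories.

    The policy is a signed sine amplitude a: the trial path is
    x = a_t * sin(pi y / D) plus per-sample execution noise, with y rising at
    constant velocity past the target. Each trial samples an exploratory
    amplitude around the current mean; the mean then moves toward explored
    amplitudes that beat a running score baseline (REINFORCE-style), at a rate
    proportional to ``aptitude``. Aptitude 0 keeps the mean amplitude at the
    visible path (score near 40); positive aptitude drifts it toward the
    rewarded mirror path.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    D = geom.target_distance
    a = float(geom.visible_amplitude)
    baseline = None
    trajectories = []
    for trial in range(n_trials):
        a_try = a + rng.normal(0.0, exploration_sd)
        t = np.linspace(0.0, trial_duration, n_samples)
        y = 1.05 * D * t / trial_duration
        x = a_try * np.sin(np.pi * np.clip(y, 0.0, D) / D)
        x = x + rng.normal(0.0, execution_noise, n_samples)
        traj = Trajectory(t=t, x=x, y=y, trial=trial)
        trajectories.append(traj)
        score = score_trajectory(traj, geom)
        if baseline is None:
            baseline = score
        a = a + aptitude * (score - baseline) / 100.0 * (a_try - a)
        baseline = 0.8 * baseline + 0.2 * score
    trial_set = TrialSet(trajectories=trajectories)
    return compute_scores(trial_set, geom)
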