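"""Synthetic study generator with the statistical structure the analysis assumes.

The generator emulates a 36-subject reward-learning study: per subject, three
task epochs (baseline, early, late) of multivariate Gaussian region time
series whose true covariance has network-block structure; subject identity
enters as a congruence perturbation A_i S A_i^T of the base covariance —
exactly the kind of offset the Riemannian centering removes — and a
connectivity change of a designated network is injected additively into the
affected epochs. Parcel centroids are drawn clustered on the unit sphere so
the spin test has a meaningful spatial layout, and behavioral learning curves
follow a single saturating "overall learning" mode with fast and slow
learners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .io import ParcellationMeta, RegionTimeSeries, ValidationError


class GenerationError(ValueError):
    """The requested configuration produced an invalid (non-SPD) truth matrix."""


@dataclass
class SyntheticStudyConfig:
    """Study-level generation parameters (defaults mirror the emulated design)."""

    n_subjects: int = 36
    n_regions: int = 120
    n_networks7: int = 7
    n_networks17: int = 17
    n_epochs: int = 3
    volumes_per_epoch: int = 210
    tr: float = 2.0
    within_network_corr: float = 0.3
    cohesion_spread: float = 0.1  # within-network correlation varies across networks
    between_network_corr: float = 0.05
    subject_offset_scale: float = 0.4
    target_network: int = 0  # index of the coarse network receiving the epoch effect
    connectivity_delta: float = 0.2
    affected_epochs: tuple[int, ...] = (1, 2)  # early and late learning
    n_trials: int = 200
    learner_mix: float = 0.5  # fraction of fast learners
    aptitude_gap: float = 10.0  # fast/slow mean separation (score points)
    aptitude_sd: float = 4.0
    trial_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.within_network_corr, self.between_network_corr):
            if not -1.0 < r < 1.0:
                raise ValidationError("correlations must lie in (-1, 1)")
        if self.n_regions < self.n_networks7:
            raise ValidationError("need at least one region per network")
        if self.n_networks17 < self.n_networks7:
            raise ValidationError("fine networks must be at least as many as coarse")
        if not 0 <= self.target_network < self.n_networks7:
            raise ValidationError("target_network out of range")
        if any(e < 0 or e >= self.n_epochs for e in self.affected_epochs):
            raise ValidationError("affected_epochs out of range")
        if not 0.0 <= self.learner_mix <= 1.0:
            raise ValidationError("learner_mix must be in [0, 1]")


@dataclass
class SyntheticStudy:
    """A complete generated study plus its ground truth."""

    config: SyntheticStudyConfig
    timeseries: list[list[RegionTimeSeries]]  # [subject][epoch]
    parcellation: ParcellationMeta
    truth_covariances: list[list[np.ndarray]]
    affected_mask: np.ndarray  # bool per region
    aptitude: np.ndarray  # per subject
    curves: np.ndarray  # subjects x trials raw scores
    epoch_names: list[str] = field(default_factory=lambda: ["baseline", "early", "late"])


def _splits(n_items: int, n_groups: int) -> list[np.ndarray]:
    return np.array_split(np.arange(n_items), n_groups)


def make_parcellation(
    R: int, n_networks7: int = 7, n_networks17: int = 17, seed: int = 0, spread: float = 0.25
) -> ParcellationMeta:
    """Clustered spherical parcellation with contiguous network blocks.

    Each coarse network gets a direction on the unit sphere; member regions
    scatter around it (or its x-mirror) with Gaussian tangent noise, giving
    von-Mises-Fisher-style concentration. Hemisphere is the sign of the final
    x coordinate. Fine (17-level) networks subdivide the coarse blocks.
    """
    if R < n_networks7:
        raise ValidationError(f"R={R} smaller than {n_networks7} networks")
    rng = np.random.default_rng(seed)
    blocks7 = _splits(R, n_networks7)
    fine_per_coarse = [len(s) for s in _splits(n_networks17, n_networks7)]

    region_ids = [f"R{i:04d}" for i in range(R)]
    net7 = np.empty(R, dtype=object)
    net17 = np.empty(R, dtype=object)
    centroids = np.empty((R, 3))
    hemisphere = np.empty(R, dtype=object)
    fine_counter = 0
    for n, block in enumerate(blocks7):
        mu = rng.normal(size=3)
        mu /= np.linalg.norm(mu)
        mu[0] = abs(mu[0])  # right-hemisphere representative; mirror for left
        for j, r in enumerate(block):
            base = mu.copy()
            if j % 2 == 0:
                base[0] = -base[0]
            v = base + spread * rng.normal(size=3)
            v /= np.linalg.norm(v)
            centroids[r] = v
            hemisphere[r] = "left" if v[0] < 0 else "right"
            net7[r] = f"Net7_{n + 1}"
        for fsub, fine_block in enumerate(_splits(len(block), fine_per_coarse[n])):
            fine_counter += 1
            for j in fine_block:
                net17[block[j]] = f"Net17_{fine_counter}"
    return ParcellationMeta(
        region_ids=region_ids,
        hemisphere=list(hemisphere),
        network7=list(net7),
        network17=list(net17),
        centroids=centroids,
    )


def _base_covariance(cfg: SyntheticStudyConfig) -> np.ndarray:
    """Block base covariance; networks differ in cohesion.

    Within-network correlations are graded across networks (mean
    ``within_network_corr``, spread ``cohesion_spread``), mirroring the fact
    that canonical functional networks differ in how tightly their regions
    covary; this heterogeneity is what makes segregated (cohesive) networks
    sit farther out on the manifold.
    """
    R = cfg.n_regions
    blocks = _splits(R, cfg.n_networks7)
    grades = np.linspace(-1.0, 1.0, cfg.n_networks7)
    B = np.full((R, R), cfg.between_network_corr)
    for n, block in enumerate(blocks):
        rho = cfg.within_network_corr + cfg.cohesion_spread * grades[n]
        if not -1.0 < rho < 1.0:
            raise ValidationError("cohesion_spread pushes correlations out of (-1, 1)")
        B[np.ix_(block, block)] = rho
    np.fill_diagonal(B, 1.0)
    return B


def _epoch_delta(cfg: SyntheticStudyConfig) -> np.ndarray:
    R = cfg.n_regions
    block = _splits(R, cfg.n_networks7)[cfg.target_network]
    D = np.zeros((R, R))
    D[np.ix_(block, block)] = cfg.connectivity_delta
    D[block, block] = 0.0  # correlations only; variances untouched
    return D


def make_covariance_structure(cfg: SyntheticStudyConfig) -> list[list[np.ndarray]]:
    """Ground-truth covariance per subject and epoch.

    Per-subject matrices are congruences A_i B A_i^T of the block base
    covariance, with A_i = expm(scale * Z_i) for a random symmetric Z_i —
    near-identity, invertible, and exactly removable by tangent-space
    centering. The epoch effect adds ``connectivity_delta`` to the target
    network's within-block correlations in the affected epochs (after the
    congruence, so only that block of the truth matrix changes).
    """
    from scipy.linalg import expm

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    R = cfg.n_regions
    B = _base_covariance(cfg)
    Delta = _epoch_delta(cfg)
    truth: list[list[np.ndarray]] = []
    for _ in range(cfg.n_subjects):
        W = rng.normal(size=(R, R))
        Z = (W + W.T) / (2.0 * np.sqrt(R))
        A = expm(cfg.subject_offset_scale * Z) if cfg.subject_offset_scale > 0 else np.eye(R)
        S_base = A @ B @ A.T
        row = []
        for j in range(cfg.n_epochs):
            S = S_base + Delta if j in cfg.affected_epochs else S_base.copy()
            S = (S + S.T) / 2.0
            w = np.linalg.eigvalsh(S)
            if w.min() <= 1e-6:
                raise GenerationError(
                    f"truth covariance not positive-definite (min eig {w.min():.2e}); "
                    "reduce connectivity_delta or correlations"
                )
            row.append(S)
        truth.append(row)
    return truth


def sample_timeseries(
    cov: np.ndarray, T: int, seed, region_ids: list[str] | None = None, tr: float = 2.0
) -> RegionTimeSeries:
    """T zero-mean multivariate Gaussian draws with the given SPD covariance."""
    cov = np.asarray(cov, float)
    if T < 2:
        raise ValidationError("need at least 2 volumes")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("covariance is not positive-definite") from exc
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((T, cov.shape[0])) @ L.T
    if region_ids is None:
        region_ids = [f"R{i:04d}" for i in range(cov.shape[0])]
    return RegionTimeSeries(values=X.T, region_ids=region_ids, tr=tr)


def make_learning_curves(
    cfg: SyntheticStudyConfig, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject trial scores and ground-truth aptitude.

    Scores follow population mean curve + aptitude_i * learning mode + noise,
    clipped to [0, 100]. The mean curve starts at the visible-path score (40)
    and saturates 25 points higher with a 50-trial time constant; the learning
    mode is the same saturating-exponential shape, so a single functional
    component carries all between-subject variation. Aptitude is a fast/slow
    mixture (means +/- aptitude_gap, SD aptitude_sd).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 202]) if seed is None else seed
    )
    t = np.arange(cfg.n_trials, dtype=float)
    mode = (1.0 - np.exp(-t / 50.0)) / (1.0 - np.exp(-(cfg.n_trials - 1) / 50.0))
    mean_curve = 40.0 + 25.0 * mode
    fast = rng.random(cfg.n_subjects) < cfg.learner_mix
    aptitude = np.where(fast, cfg.aptitude_gap, -cfg.aptitude_gap) + rng.normal(
        0.0, cfg.aptitude_sd, cfg.n_subjects
    )
    noise = rng.normal(0.0, cfg.trial_noise_sd, (cfg.n_subjects, cfg.n_trials))
    curves = np.clip(mean_curve + aptitude[:, None] * mode + noise, 0.0, 100.0)
    return curves, aptitude


def make_study(cfg: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate the full synthetic study (time series, parcellation, truth, curves)."""
    parcellation = make_parcellation(
        cfg.n_regions, cfg.n_networks7, cfg.n_networks17, seed=cfg.seed
    )
    truth = make_covariance_structure(cfg)
    ss = np.random.SeedSequence([cfg.seed, 303])
    child_seeds = ss.spawn(cfg.n_subjects * cfg.n_epochs)
    timeseries: list[list[RegionTimeSeries]] = []
    for i in range(cfg.n_subjects):
        row = []
        for j in range(cfg.n_epochs):
            row.append(
                sample_timeseries(
                    truth[i][j],
                    cfg.volumes_per_epoch,
                    child_seeds[i * cfg.n_epochs + j],
                    region_ids=parcellation.region_ids,
                    tr=cfg.tr,
                )
            )
        timeseries.append(row)
    curves, aptitude = make_learning_curves(cfg)
    block = _splits(cfg.n_regions, cfg.n_networks7)[cfg.target_network]
    mask = np.zeros(cfg.n_regions, dtype=bool)
    mask[block] = True
    epoch_names = ["baseline", "early", "late"][: cfg.n_epochs] + [
        f"epoch{j}" for j in range(3, cfg.n_epochs)
    ]
    return SyntheticStudy(
        config=cfg,
        timeseries=timeseries,
        parcellation=parcellation,
        truth_covariances=truth,
        affected_mask=mask,
        aptitude=aptitude,
        curves=curves,
        epoch_names=epoch_names,
    )


def write_fixtures(study: SyntheticStudy, out_dir: str | Path) -> list[Path]:
    """Write the study as the canonical TSV fixture files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    p = out_dir / "parcellation.tsv"
    cio.write_parcellation(study.parcellation, p)
    written.append(p)
    for i, row in enumerate(study.timeseries):
        for j, ts in enumerate(row):
            p = out_dir / f"sub{i:02d}_{study.epoch_names[j]}_timeseries.tsv"
            cio.write_timeseries(ts, p)
            written.append(p)
    import pandas as pd

    scores = pd.DataFrame(
        study.curves.T, columns=[f"sub{i:02d}" for i in range(study.curves.shape[0])]
    )
    scores.insert(0, "trial", np.arange(study.curves.shape[1]))
    p = out_dir / "trial_scores.tsv"
    scores.to_csv(p, sep="\t", index=False, float_format=cio.FLOAT_FMT)
    written.append(p)
    return written
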