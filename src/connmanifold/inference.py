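"""Epoch contrasts, seed-connectivity contrasts, and spin-test inference.

Region-wise paired t-tests (two-tailed, Benjamini-Hochberg FDR at q = 0.05)
compare eccentricity or seed-connectivity maps between task epochs. Network-
level brain-behavior correlations are tested against a spatial-
autocorrelation-preserving null built by randomly rotating parcel centroids
on the sphere (mirrored across hemispheres) and uniquely reassigning region
values (Vasa-style spin permutation); a network is called significant only
if it beats both the spin null and a conventional test against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ParcellationMeta, ValidationError
from .manifold import EccentricityMap
from .spd import CovarianceMatrix


@dataclass
class ContrastMap:
    """Per-region paired-contrast statistics."""

    region_ids: list[str]
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray  # BH-FDR pass at q
    label: str
    q: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "t": self.t,
                "p": self.p,
                "significant": self.significant.astype(int),
            }
        )


@dataclass
class NetworkSummary:
    """Mean statistic per network label."""

    networks: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"network": self.networks, "statistic": self.values})


@dataclass
class SpinNull:
    """Null network statistics from spin permutations (networks x n_spins)."""

    networks: list[str]
    null: np.ndarray
    n_spins: int
    seed: int


def bh_fdr(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    reject, *_ = multipletests(np.asarray(p, float), alpha=q, method="fdr_bh")
    return reject


def paired_contrast(
    A: list[EccentricityMap] | np.ndarray,
    B: list[EccentricityMap] | np.ndarray,
    q: float = 0.05,
    label: str = "B>A",
    region_ids: list[str] | None = None,
) -> ContrastMap:
    """Region-wise paired two-tailed t-test of B - A across subjects, with FDR.

    Positive t marks expansion (larger values) in B. Regions whose paired
    differences have zero variance get t = 0, p = 1 with a warning.
    """

    def as_matrix(maps):
        if isinstance(maps, np.ndarray):
            return maps, None
        return np.array([m.values for m in maps]), list(maps[0].region_ids)

    MA, ids_a = as_matrix(A)
    MB, ids_b = as_matrix(B)
    if MA.shape != MB.shape:
        raise ValidationError("A and B must have matching subjects and regions")
    if MA.shape[0] < 3:
        raise ValidationError("need at least 3 subjects for a paired t-test")
    region_ids = region_ids or ids_a or ids_b or [str(i) for i in range(MA.shape[1])]

    diff = MB - MA
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var):
        warnings.warn(f"{int(zero_var.sum())} region(s) with zero-variance differences; p set to 1")
    t = np.zeros(diff.shape[1])
    p = np.ones(diff.shape[1])
    ok = ~zero_var
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    return ContrastMap(
        region_ids=region_ids, t=t, p=p, significant=bh_fdr(p, q), label=label, q=q
    )


def seed_contrast(
    covs_a: list[CovarianceMatrix],
    covs_b: list[CovarianceMatrix],
    seed_regions: list[str],
    meta: ParcellationMeta | None = None,
    q: float = 0.05,
    label: str = "B>A",
) -> tuple[ContrastMap, NetworkSummary | None]:
    """Paired contrast of seed-connectivity maps between two epochs.

    A subject's seed map is the mean covariance row over the seed regions.
    The returned map is unthresholded (``significant`` still records the FDR
    mask); if parcellation metadata is given, the 17-network mean t per
    network is summarized alongside.
    """
    if not seed_regions:
        raise ValidationError("seed_regions must be nonempty")
    if len(covs_a) != len(covs_b):
        raise ValidationError("epochs must have matching subjects")
    ids = covs_a[0].region_ids
    try:
        seed_idx = [ids.index(s) for s in seed_regions]
    except ValueError as exc:
        raise ValidationError(f"unknown seed region: {exc}") from exc

    def seed_maps(covs):
        return np.array([c.values[seed_idx].mean(axis=0) for c in covs])

    cmap = paired_contrast(seed_maps(covs_a), seed_maps(covs_b), q=q, label=label, region_ids=ids)
    summary = None
    if meta is not None:
        labels = meta.network_labels(17)
        nets = sorted(set(labels))
        means = np.array([cmap.t[labels == net].mean() for net in nets])
        summary = NetworkSummary(networks=nets, values=means)
    return cmap, summary


# ---------------------------------------------------------------------------
# spin test
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation (QR of a Gaussian matrix, det +1)."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def spin_permutations(
    meta: ParcellationMeta, n_spins: int, seed: int
) -> np.ndarray:
    """Vasa-style spin permutations of the cortical regions.

    Each spin draws one random rotation, applies it to the right hemisphere
    and its x-mirrored version to the left, then reassigns regions within
    each hemisphere by greedy unique nearest-centroid matching in random
    order — a true permutation, so every spin preserves the multiset of
    values. Subcortical regions map to themselves.

    Returns an (n_spins, n_regions) integer array: permuted map = values[perm].
    """
    if n_spins < 1:
        raise ValidationError("n_spins must be >= 1")
    rng = np.random.default_rng(seed)
    n = meta.n_regions
    hemi = np.asarray(meta.hemisphere)
    mirror = np.diag([-1.0, 1.0, 1.0])
    perms = np.tile(np.arange(n), (n_spins, 1))
    for s in range(n_spins):
        Q = _random_rotation(rng)
        for side, rot in (("right", Q), ("left", mirror @ Q @ mirror)):
            idx = np.flatnonzero(hemi == side)
            if idx.size == 0:
                continue
            C = meta.centroids[idx]
            rotated = C @ rot.T
            sim = rotated @ C.T  # cosine similarity: rotated i vs original j
            order = rng.permutation(idx.size)
            taken = np.zeros(idx.size, dtype=bool)
            for i in order:
                row = np.where(taken, -np.inf, sim[i])
                j = int(np.argmax(row))
                taken[j] = True
                # region idx[i]'s rotated position lands on original idx[j]:
                # it receives region idx[j]'s value
                perms[s, idx[i]] = idx[j]
    return perms


def spin_null(
    region_values: np.ndarray,
    meta: ParcellationMeta,
    n_spins: int = 1000,
    seed: int = 0,
    network_level: int = 17,
) -> SpinNull:
    """Null distribution of per-network means under spin permutations."""
    values = np.asarray(region_values, float)
    if values.shape[0] != meta.n_regions:
        raise ValidationError("region_values length mismatch")
    perms = spin_permutations(meta, n_spins, seed)
    labels = meta.network_labels(network_level)
    nets = sorted(set(labels))
    null = np.empty((len(nets), n_spins))
    permuted = values[perms]  # n_spins x regions
    for k, net in enumerate(nets):
        null[k] = permuted[:, labels == net].mean(axis=1)
    return SpinNull(networks=nets, null=null, n_spins=n_spins, seed=seed)


def _spin_p(observed: float, null: np.ndarray) -> float:
    """Two-sided permutation p with the (b + 1) / (m + 1) convention."""
    m = null.size
    hi = (1 + np.sum(null >= observed)) / (m + 1)
    lo = (1 + np.sum(null <= observed)) / (m + 1)
    return float(min(1.0, 2.0 * min(hi, lo)))


def network_behavior_test(
    delta_ecc: np.ndarray,
    scores: np.ndarray,
    meta: ParcellationMeta,
    n_spins: int = 1000,
    seed: int = 0,
    q: float = 0.05,
    network_level: int = 17,
) -> pd.DataFrame:
    """Network-level test of the brain-behavior correlation map.

    ``delta_ecc`` is subjects x regions (eccentricity change between two
    epochs); ``scores`` the per-subject learning scores. Each region's
    Pearson correlation with the score is averaged within networks; the
    network mean is ranked against its spin null (p_spin). Additionally the
    subject-level correlation of network-mean eccentricity change with the
    score is tested against zero (p_zero). A network is significant only if
    its spin test passes at level q and its zero-test survives BH-FDR across
    networks — the dual rule: an effect must be both spatially specific and
    different from zero.
    """
    delta_ecc = np.asarray(delta_ecc, float)
    scores = np.asarray(scores, float)
    n_sub, n_reg = delta_ecc.shape
    if scores.shape != (n_sub,):
        raise ValidationError("scores must match delta_ecc subjects")
    if n_sub < 5:
        raise ValidationError("need at least 5 subjects for stable correlations")
    if n_reg != meta.n_regions:
        raise ValidationError("delta_ecc regions mismatch parcellation")

    # region-level correlation map across subjects
    zs = (scores - scores.mean()) / scores.std()
    E = delta_ecc - delta_ecc.mean(axis=0)
    sd = E.std(axis=0)
    sd[sd == 0] = np.inf  # flat regions correlate 0
    r_map = (E / sd).T @ zs / n_sub

    labels = meta.network_labels(network_level)
    nets = sorted(set(labels))
    obs = np.array([r_map[labels == net].mean() for net in nets])

    nullobj = spin_null(r_map, meta, n_spins=n_spins, seed=seed, network_level=network_level)
    p_spin = np.array([_spin_p(obs[k], nullobj.null[k]) for k in range(len(nets))])

    p_zero = np.empty(len(nets))
    r_zero = np.empty(len(nets))
    for k, net in enumerate(nets):
        net_mean = delta_ecc[:, labels == net].mean(axis=1)
        if np.std(net_mean) == 0:
            r_zero[k], p_zero[k] = 0.0, 1.0
        else:
            r_zero[k], p_zero[k] = stats.pearsonr(net_mean, scores)

    sig = (p_spin <= q) & bh_fdr(p_zero, q)
    return pd.DataFrame(
        {
            "network": nets,
            "r": obs,
            "r_subject": r_zero,
            "p_spin": p_spin,
            "p_zero": p_zero,
            "significant": sig.astype(int),
        }
    )
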