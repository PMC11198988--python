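"""Connectivity-manifold construction, alignment and eccentricity.

A centered connectivity matrix is row-thresholded (top fraction of each row's
off-diagonal connections, by signed value), converted to a cosine-similarity
affinity matrix, and embedded by PCA. Individual embeddings are aligned to a
group baseline template with orthogonal Procrustes (rotation/reflection only
— no scaling or translation, so inter-region distances are preserved), and
each region's eccentricity is its Euclidean distance from the manifold
centroid at the origin. High eccentricity marks segregated regions; low
eccentricity marks regions that integrate across networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .io import ValidationError
from .spd import CovarianceMatrix, geometric_mean


@dataclass
class AffinityMatrix:
    """Cosine similarities of row-thresholded connectivity profiles."""

    values: np.ndarray
    region_ids: list[str]
    threshold_fraction: float

    def __post_init__(self) -> None:
        v = self.values
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValidationError("affinity not symmetric")
        if np.any(np.abs(np.diag(v) - 1.0) > 1e-10):
            raise ValidationError("affinity diagonal must be 1")
        if v.min() < -1.0 - 1e-10 or v.max() > 1.0 + 1e-10:
            raise ValidationError("affinity values must lie in [-1, 1]")


@dataclass
class Embedding:
    """Region coordinates on the top principal components of an affinity matrix."""

    coords: np.ndarray  # regions x components
    explained_variance: np.ndarray  # per-component fraction
    region_ids: list[str]
    aligned_to: str | None = None
    component_correlations: np.ndarray | None = None  # vs. alignment target

    def __post_init__(self) -> None:
        ev = np.asarray(self.explained_variance, float)
        if np.any(np.diff(ev) > 1e-12):
            raise ValidationError("explained_variance must be non-increasing")
        if np.any(ev < -1e-12) or ev.sum() > 1.0 + 1e-9:
            raise ValidationError("explained_variance fractions invalid")

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def threshold_rows(C: np.ndarray, top_fraction: float) -> np.ndarray:
    """Keep the top fraction of each row's off-diagonal entries by signed value.

    Retains ceil(top_fraction * (R - 1)) entries per row; ties at the cutoff
    are broken toward the lower region index. The diagonal is excluded from
    thresholding and zeroed. The result is generally asymmetric.
    """
    C = np.asarray(C, float)
    R = C.shape[0]
    if not 0.0 < top_fraction <= 1.0:
        raise ValidationError("top_fraction must be in (0, 1]")
    k = int(np.ceil(top_fraction * (R - 1)))
    out = np.zeros_like(C)
    idx = np.arange(R)
    for i in range(R):
        row = C[i]
        others = idx[idx != i]
        # stable sort: by descending value, then ascending index
        order = others[np.lexsort((others, -row[others]))]
        keep = order[:k]
        out[i, keep] = row[keep]
    return out


def build_affinity(C: CovarianceMatrix | np.ndarray, top_fraction: float = 0.10,
                   region_ids: list[str] | None = None) -> AffinityMatrix:
    """Row-threshold a connectivity matrix and take cosine similarity between rows."""
    if isinstance(C, CovarianceMatrix):
        region_ids = C.region_ids
        values = C.values
    else:
        values = np.asarray(C, float)
        if region_ids is None:
            region_ids = [str(i) for i in range(values.shape[0])]
    W = threshold_rows(values, top_fraction)
    norms = np.linalg.norm(W, axis=1)
    if np.any(norms == 0):
        bad = region_ids[int(np.argmin(norms))]
        raise ValidationError(f"row {bad!r} is entirely zero after thresholding")
    U = W / norms[:, None]
    A = U @ U.T
    A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(A, 1.0)
    return AffinityMatrix(values=A, region_ids=list(region_ids), threshold_fraction=top_fraction)


def embed(A: AffinityMatrix, d: int = 3) -> Embedding:
    """PCA of the column-mean-centered affinity matrix.

    Coordinates are the region scores on the top ``d`` components; explained
    variance comes from the squared singular values. Sign convention: each
    component is oriented so that its largest-magnitude loading is positive
    (ties to the first occurrence), making the embedding deterministic.
    """
    X = A.values - A.values.mean(axis=0, keepdims=True)
    R = X.shape[0]
    if d > R:
        raise ValidationError(f"d={d} exceeds {R} regions")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s[0] > 0 else 0
    if d > rank:
        raise ValidationError(f"d={d} exceeds affinity rank {rank}")
    total = float(np.sum(s**2))
    coords = U[:, :d] * s[:d]
    ev = s[:d] ** 2 / total
    for c in range(d):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            coords[:, c] = -coords[:, c]
    return Embedding(coords=coords, explained_variance=ev, region_ids=list(A.region_ids))


def build_template(
    baseline_covs: list[CovarianceMatrix],
    top_fraction: float = 0.10,
    d: int = 3,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> Embedding:
    """Group baseline template: geometric mean -> affinity -> PCA embedding."""
    if not baseline_covs:
        raise ValidationError("need at least one baseline covariance")
    gm = geometric_mean([c.values for c in baseline_covs], tol=tol, max_iter=max_iter)
    A = build_affinity(gm, top_fraction, region_ids=baseline_covs[0].region_ids)
    emb = embed(A, d)
    emb.aligned_to = "template"
    return emb


def align(source: Embedding, target: Embedding) -> Embedding:
    """Orthogonal Procrustes alignment of ``source`` onto ``target``.

    Finds the rotation/reflection Q minimizing ||source @ Q - target||_F and
    returns the transformed embedding. Per-component Pearson correlations with
    the target are recorded as an alignment-quality diagnostic.
    """
    if source.coords.shape != target.coords.shape:
        raise ValidationError("embedding dimension mismatch")
    if source.region_ids != target.region_ids:
        raise ValidationError("embeddings must share region ids")
    Q, _ = orthogonal_procrustes(source.coords, target.coords)
    aligned = source.coords @ Q
    corrs = np.array(
        [
            np.corrcoef(aligned[:, c], target.coords[:, c])[0, 1]
            if np.std(aligned[:, c]) > 0 and np.std(target.coords[:, c]) > 0
            else np.nan
            for c in range(aligned.shape[1])
        ]
    )
    return Embedding(
        coords=aligned,
        explained_variance=source.explained_variance,
        region_ids=source.region_ids,
        aligned_to=target.aligned_to or "target",
        component_correlations=corrs,
    )


@dataclass
class EccentricityMap:
    """Per-region distance from the manifold centroid (the origin)."""

    values: np.ndarray
    region_ids: list[str]
    subject: str | None = None
    epoch: str | None = None


def eccentricity(e: Embedding, subject: str | None = None, epoch: str | None = None) -> EccentricityMap:
    """Euclidean norm of each region's (aligned) manifold coordinates.

    The manifold centroid is the origin: PCA scores are centered, so the
    template's empirical centroid coincides with (0, 0, 0), and a fixed origin
    keeps eccentricity comparable across epochs after Procrustes alignment.
    """
    return EccentricityMap(
        values=np.linalg.norm(e.coords, axis=1),
        region_ids=list(e.region_ids),
        subject=subject,
        epoch=epoch,
    )
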