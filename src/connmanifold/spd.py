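"""Covariance estimation and Riemannian centering on the SPD manifold.

Functional-connectivity matrices are symmetric positive-definite (SPD) and are
treated under the affine-invariant Riemannian metric. Centering removes
subject-specific covariance offsets by (1) projecting each subject's epoch
matrices onto the tangent space at the subject's geometric mean, (2)
parallel-transporting the tangent vectors to the grand geometric mean, and
(3) mapping back to the manifold. The transport used is the congruence by
G_i = Sgm^{1/2} Si^{-1/2}, under which the whole three-step composite is
mathematically a congruence map S -> G_i S G_i^T; the three-step form is the
shipped implementation and the one-step congruence serves as an independent
oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import LedoitWolf

from .io import RegionTimeSeries, ValidationError

EIG_FLOOR = 1e-12


class ConditioningError(ValueError):
    """An SPD operation hit an eigenvalue at or below the admissible floor."""


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class CovarianceMatrix:
    """A symmetric positive-definite region-by-region covariance."""

    values: np.ndarray
    region_ids: list[str]
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError("covariance must be square")
        if len(self.region_ids) != n:
            raise ValidationError("region_ids length mismatch")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValidationError("covariance not symmetric to 1e-10")
        if np.any(np.diag(self.values) <= 0):
            raise ValidationError("covariance diagonal must be positive")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValidationError("shrinkage must be in [0, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class TangentVector:
    """A symmetric matrix living in the tangent space at an SPD base point."""

    values: np.ndarray
    base: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.base = np.asarray(self.base, dtype=float)
        if self.values.shape != self.base.shape:
            raise ValidationError("tangent vector and base dimension mismatch")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValidationError("tangent vector not symmetric to 1e-10")


@dataclass
class CovarianceSet:
    """A complete subject-by-epoch grid of covariance matrices.

    After :func:`center_set`, ``centered`` holds the grid mapped to the grand
    mean, and the intermediates (subject means, grand mean, tangent vectors,
    transporters) are retained for inspection and testing.
    """

    matrices: list[list[CovarianceMatrix]]  # [subject][epoch]
    subject_means: list[np.ndarray] | None = None
    grand_mean: np.ndarray | None = None
    transporters: list[np.ndarray] | None = None
    tangent: list[list[TangentVector]] | None = None
    tangent_centered: list[list[TangentVector]] | None = None
    centered: list[list[CovarianceMatrix]] | None = None
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.matrices or not self.matrices[0]:
            raise ValidationError("covariance set is empty")
        n_epochs = len(self.matrices[0])
        ids = self.matrices[0][0].region_ids
        for i, row in enumerate(self.matrices):
            if len(row) != n_epochs:
                raise ValidationError(
                    f"subject {i} has {len(row)} epochs, expected {n_epochs} (missing cells rejected)"
                )
            for mat in row:
                if mat.region_ids != ids:
                    raise ValidationError("all matrices must share region_ids")
        self.region_ids = list(ids)

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def n_epochs(self) -> int:
        return len(self.matrices[0])


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def shrinkage_covariance(ts: RegionTimeSeries) -> CovarianceMatrix:
    """Ledoit-Wolf shrinkage covariance of a region time series.

    Shrinks the sample covariance toward the scaled identity with a
    data-driven intensity, guaranteeing an SPD estimate even when regions
    outnumber volumes. Constant (zero-variance) regions are rejected.
    """
    X = ts.values.T  # samples x features
    variances = X.var(axis=0)
    if np.any(variances == 0):
        bad = ts.region_ids[int(np.argmin(variances))]
        raise ValidationError(f"region {bad!r} has zero variance")
    lw = LedoitWolf(assume_centered=False).fit(X)
    cov = (lw.covariance_ + lw.covariance_.T) / 2.0
    return CovarianceMatrix(values=cov, region_ids=ts.region_ids, shrinkage=float(lw.shrinkage_))


def _eigh_spd(A: np.ndarray, require_pd: bool) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(A, dtype=float)
    if np.max(np.abs(A - A.T)) > 1e-8:
        raise ValidationError("matrix not symmetric")
    w, V = np.linalg.eigh((A + A.T) / 2.0)
    if require_pd and w.min() <= EIG_FLOOR:
        raise ConditioningError(
            f"eigenvalue {w.min():.3e} at or below floor {EIG_FLOOR:g}"
        )
    return w, V


def spd_matrix_function(A: np.ndarray, f: str) -> np.ndarray:
    """Apply ``sqrt``, ``invsqrt``, ``log`` or ``exp`` spectrally to a symmetric matrix.

    ``sqrt``/``invsqrt``/``log`` require positive-definiteness (eigenvalues
    above 1e-12; below that is an error, never a silent clamp); ``exp`` maps
    any symmetric matrix into the SPD cone.
    """
    funcs = {"sqrt": np.sqrt, "invsqrt": lambda w: 1.0 / np.sqrt(w), "log": np.log, "exp": np.exp}
    if f not in funcs:
        raise ValueError(f"unknown matrix function {f!r}")
    w, V = _eigh_spd(A, require_pd=f != "exp")
    out = (V * funcs[f](w)) @ V.T
    return (out + out.T) / 2.0


def affine_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant geodesic distance ||log(A^{-1/2} B A^{-1/2})||_F."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValidationError("dimension mismatch")
    Aih = spd_matrix_function(A, "invsqrt")
    M = Aih @ B @ Aih
    w, _ = _eigh_spd(M, require_pd=True)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def geometric_mean(
    mats: list[np.ndarray], tol: float = 1e-10, max_iter: int = 200
) -> np.ndarray:
    """Karcher (Frechet) mean under the affine-invariant metric.

    Fixed-point iteration M <- M^{1/2} exp(mean_k log(M^{-1/2} S_k M^{-1/2})) M^{1/2},
    initialized at the arithmetic mean, unit step. At convergence the mean of
    the tangent logs at M vanishes (Frobenius norm below ``tol``).
    """
    mats = [np.asarray(m, float) for m in mats]
    if not mats:
        raise ValidationError("need at least one matrix")
    if len(mats) == 1:
        return mats[0].copy()
    M = np.mean(mats, axis=0)
    grad_norm = np.inf
    for _ in range(max_iter):
        Mh = spd_matrix_function(M, "sqrt")
        Mih = spd_matrix_function(M, "invsqrt")
        T = np.mean([spd_matrix_function(Mih @ S @ Mih, "log") for S in mats], axis=0)
        grad_norm = float(np.linalg.norm(T))
        M = Mh @ spd_matrix_function(T, "exp") @ Mh
        M = (M + M.T) / 2.0
        if grad_norm < tol:
            return M
    raise ConditioningError(
        f"Karcher mean did not converge in {max_iter} iterations (gradient norm {grad_norm:.3e})"
    )


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------


def log_map(base: np.ndarray, S: np.ndarray) -> TangentVector:
    """Riemannian log of S at ``base``: base^{1/2} log(base^{-1/2} S base^{-1/2}) base^{1/2}."""
    Bh = spd_matrix_function(base, "sqrt")
    Bih = spd_matrix_function(base, "invsqrt")
    T = Bh @ spd_matrix_function(Bih @ S @ Bih, "log") @ Bh
    return TangentVector(values=(T + T.T) / 2.0, base=base)


def exp_map(base: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Riemannian exp of tangent vector T at ``base`` (inverse of log_map)."""
    Bh = spd_matrix_function(base, "sqrt")
    Bih = spd_matrix_function(base, "invsqrt")
    S = Bh @ spd_matrix_function(Bih @ T @ Bih, "exp") @ Bh
    return (S + S.T) / 2.0


def center_set(
    cov_set: CovarianceSet, tol: float = 1e-10, max_iter: int = 200
) -> CovarianceSet:
    """Center a subject-by-epoch covariance grid at the grand geometric mean.

    For subject i with epoch matrices S_ij and geometric mean Si:

        T_ij   = Si^{1/2} log(Si^{-1/2} S_ij Si^{-1/2}) Si^{1/2}     (log map)
        T^c_ij = G_i T_ij G_i^T,  G_i = Sgm^{1/2} Si^{-1/2}           (transport)
        S^c_ij = Sgm^{1/2} exp(Sgm^{-1/2} T^c_ij Sgm^{-1/2}) Sgm^{1/2} (exp map)

    where Sgm is the geometric mean over all subjects and epochs. Each
    subject's centered matrices then have geometric mean Sgm, while all
    within-subject affine distances are preserved.
    """
    S = [[m.values for m in row] for row in cov_set.matrices]
    n_sub = len(S)
    try:
        subj_means = [geometric_mean(row, tol=tol, max_iter=max_iter) for row in S]
        grand = geometric_mean([m for row in S for m in row], tol=tol, max_iter=max_iter)
    except ConditioningError as exc:
        raise ConditioningError(f"mean computation failed: {exc}") from exc

    Gh = spd_matrix_function(grand, "sqrt")

    transporters: list[np.ndarray] = []
    tangent: list[list[TangentVector]] = []
    tangent_centered: list[list[TangentVector]] = []
    centered: list[list[CovarianceMatrix]] = []
    for i in range(n_sub):
        Si = subj_means[i]
        G = Gh @ spd_matrix_function(Si, "invsqrt")
        transporters.append(G)
        t_row: list[TangentVector] = []
        tc_row: list[TangentVector] = []
        c_row: list[CovarianceMatrix] = []
        for j, Sij in enumerate(S[i]):
            try:
                T = log_map(Si, Sij)
                Tc_vals = G @ T.values @ G.T
                Tc = TangentVector(values=(Tc_vals + Tc_vals.T) / 2.0, base=grand)
                Sc = exp_map(grand, Tc.values)
            except ConditioningError as exc:
                raise ConditioningError(f"subject {i}, epoch {j}: {exc}") from exc
            t_row.append(T)
            tc_row.append(Tc)
            c_row.append(
                CovarianceMatrix(
                    values=Sc,
                    region_ids=cov_set.region_ids,
                    shrinkage=cov_set.matrices[i][j].shrinkage,
                )
            )
        tangent.append(t_row)
        tangent_centered.append(tc_row)
        centered.append(c_row)

    return CovarianceSet(
        matrices=cov_set.matrices,
        subject_means=subj_means,
        grand_mean=grand,
        transporters=transporters,
        tangent=tangent,
        tangent_centered=tangent_centered,
        centered=centered,
    )
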