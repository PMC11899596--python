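"""Subject-level connectivity estimation and combination.

From a parcellated time series (timepoints x parcels) this module derives
connectivity matrices — full Pearson correlation, Ledoit-Wolf shrunk
covariance, partial correlation, and tangent-space matrices around a group
reference on the manifold of symmetric positive-definite (SPD) matrices —
and combines matrices across task conditions (averages and contrasts).

Tangent-space parametrization represents each subject's SPD covariance
``C`` as ``logm(G^{-1/2} C G^{-1/2})`` where ``G`` is the affine-invariant
geometric mean of the group's covariances.  Deviations from the reference
then live in a vector space where ordinary linear statistics apply, which
is why it tends to be more sensitive to inter-subject differences than raw
(partial) correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcellatedTimeSeries",
    "ConnectivityMatrix",
    "TangentReference",
    "pearson_connectivity",
    "ledoit_wolf_covariance",
    "ledoit_wolf_shrinkage",
    "partial_correlation",
    "geometric_mean",
    "tangent_embed",
    "tangent_to_covariance",
    "average_matrices",
    "contrast_matrices",
]

KINDS = ("correlation", "partial", "covariance", "tangent", "average", "contrast")

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class ParcellatedTimeSeries:
    """BOLD-like signal, one column per parcel."""

    subject_id: str
    values: np.ndarray  # (T, P)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("time series must be a 2-D (timepoints x parcels) array")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need at least 2 timepoints and 2 parcels")
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite values in time series of {self.subject_id!r}")
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric parcel x parcel matrix of a single subject."""

    subject_id: str
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {KINDS}")
        if not np.isfinite(v).all():
            raise ValueError("non-finite values in connectivity matrix")
        if np.abs(v - v.T).max() > 1e-8:
            raise ValueError("connectivity matrix is not symmetric")
        v = 0.5 * (v + v.T)  # kill residual asymmetry from floating point
        object.__setattr__(self, "values", v)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


def _as_spd(mat: np.ndarray, floor_rel: float = 1e-10, name: str = "matrix") -> np.ndarray:
    """Validate symmetry and positive definiteness, flooring tiny eigenvalues.

    Eigenvalues below ``floor_rel * lambda_max`` are raised to that floor
    with a warning rather than failing outright; genuinely indefinite input
    (negative eigenvalues beyond the floor) raises.
    """
    A = np.asarray(mat, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or np.abs(A - A.T).max() > 1e-8:
        raise ValueError(f"{name} must be a symmetric square matrix")
    A = 0.5 * (A + A.T)
    w, V = np.linalg.eigh(A)
    lam_max = w[-1]
    if lam_max <= 0:
        raise ValueError(f"{name} is not positive definite")
    floor = floor_rel * lam_max
    if w[0] < -1e-8 * lam_max:
        raise ValueError(f"{name} has negative eigenvalues (min {w[0]:.3e})")
    if w[0] < floor:
        warnings.warn(
            f"{name}: flooring {int((w < floor).sum())} eigenvalue(s) to "
            f"{floor:.3e} for SPD validity",
            stacklevel=2,
        )
        w = np.maximum(w, floor)
        A = (V * w) @ V.T
        A = 0.5 * (A + A.T)
    return A


def _sym_logm(A: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (A + A.T))
    if w[0] <= 0:
        raise ValueError("matrix logarithm requires a positive-definite argument")
    L = (V * np.log(w)) @ V.T
    return 0.5 * (L + L.T)


def _sym_expm(A: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (A + A.T))
    E = (V * np.exp(w)) @ V.T
    return 0.5 * (E + E.T)


def _spd_power(A: np.ndarray, power: float) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (A + A.T))
    if w[0] <= 0:
        raise ValueError("matrix power requires a positive-definite argument")
    R = (V * w**power) @ V.T
    return 0.5 * (R + R.T)


def pearson_connectivity(ts: ParcellatedTimeSeries) -> ConnectivityMatrix:
    """Full Pearson correlation matrix with unit diagonal.

    Raises a descriptive error naming the offending parcel if any column
    has zero variance (correlation undefined).
    """
    X = ts.values
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance parcel column(s) {dead.tolist()} in subject "
            f"{ts.subject_id!r}: correlation undefined"
        )
    C = np.corrcoef(X, rowvar=False)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return ConnectivityMatrix(subject_id=ts.subject_id, values=C, kind="correlation")


def ledoit_wolf_shrinkage(X: np.ndarray) -> float:
    """Optimal shrinkage intensity of the Ledoit-Wolf (2004) estimator.

    ``X`` is (n, p) raw data; columns are centred internally and the sample
    covariance uses the 1/n convention.  The intensity is
    ``min(beta^2, delta^2) / delta^2`` with ``delta^2 = ||S - mu I||_F^2 / p``
    and ``beta^2`` the (clipped) estimate of the mean squared error of S,
    guaranteeing a value in [0, 1].
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    mu = np.trace(S) / p
    delta2 = ((S - mu * np.eye(p)) ** 2).sum() / p
    if delta2 == 0.0:  # sample covariance already equals the target
        return 0.0
    sq_norms = np.einsum("ij,ij->i", Xc, Xc)
    beta2 = ((sq_norms**2).sum() / n - (S**2).sum()) / (n * p)
    beta2 = min(max(beta2, 0.0), delta2)
    return beta2 / delta2


def ledoit_wolf_covariance(
    ts: ParcellatedTimeSeries,
) -> tuple[ConnectivityMatrix, float]:
    """Ledoit-Wolf shrunk covariance ``(1 - a) S + a mu I`` and intensity a.

    The convex combination of the sample covariance with its scaled-identity
    target keeps the estimate well-conditioned (strictly positive definite
    for any non-constant data), which the tangent-space pipeline requires.
    """
    X = ts.values
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    mu = np.trace(S) / p
    if mu == 0.0:
        raise ValueError(
            f"all-constant time series for subject {ts.subject_id!r}: "
            "covariance is degenerate"
        )
    alpha = ledoit_wolf_shrinkage(X)
    shrunk = (1.0 - alpha) * S + alpha * mu * np.eye(p)
    shrunk = 0.5 * (shrunk + shrunk.T)
    return (
        ConnectivityMatrix(subject_id=ts.subject_id, values=shrunk, kind="covariance"),
        float(alpha),
    )


def partial_correlation(cov: ConnectivityMatrix) -> ConnectivityMatrix:
    """Partial correlations from a covariance via the precision matrix.

    rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj) with Theta = cov^{-1}.
    """
    if cov.kind != "covariance":
        raise ValueError("partial_correlation expects a covariance-kind matrix")
    A = _as_spd(cov.values, name="covariance")
    theta = np.linalg.inv(A)
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(0.5 * (rho + rho.T), -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return ConnectivityMatrix(subject_id=cov.subject_id, values=rho, kind="partial")


def geometric_mean(
    mats: list[np.ndarray],
    tol: float = 1e-7,
    max_iter: int = 50,
    return_info: bool = False,
):
    """Affine-invariant geometric mean of SPD matrices.

    Fixed-point iteration
    ``G <- G^{1/2} expm(mean_i logm(G^{-1/2} C_i G^{-1/2})) G^{1/2}``,
    initialised at the arithmetic mean and stopped when the Frobenius norm
    of the mean log falls below ``tol``.  For a single input the matrix
    itself is returned; for commuting inputs this reduces to the
    element-wise scalar geometric mean in the shared eigenbasis.
    """
    if len(mats) == 0:
        raise ValueError("geometric_mean needs at least one matrix")
    mats = [_as_spd(np.asarray(M, dtype=float), name=f"input {k}") for k, M in enumerate(mats)]
    P = mats[0].shape[0]
    if any(M.shape != (P, P) for M in mats):
        raise ValueError("all matrices must share the same dimension")
    if len(mats) == 1:
        G = mats[0]
        return (G, {"converged": True, "n_iter": 0, "resid": 0.0}) if return_info else G
    G = sum(mats) / len(mats)
    converged = False
    resid = np.inf
    for it in range(1, max_iter + 1):
        G_half = _spd_power(G, 0.5)
        G_ihalf = _spd_power(G, -0.5)
        L = np.zeros_like(G)
        for C in mats:
            L += _sym_logm(G_ihalf @ C @ G_ihalf)
        L /= len(mats)
        resid = float(np.linalg.norm(L, "fro"))
        if resid < tol:
            converged = True
            break
        G = G_half @ _sym_expm(L) @ G_half
        G = 0.5 * (G + G.T)
    if not converged:
        warnings.warn(
            f"geometric_mean did not reach tol={tol:g} in {max_iter} iterations "
            f"(residual {resid:.3e}); returning last iterate",
            stacklevel=2,
        )
    if return_info:
        return G, {"converged": converged, "n_iter": it, "resid": resid}
    return G


@dataclass(frozen=True)
class TangentReference:
    """Group reference point for tangent-space embedding.

    ``G`` is the geometric mean of the covariances it was fitted on and
    ``whitener = G^{-1/2}``, so ``whitener @ G @ whitener == I``.
    """

    G: np.ndarray
    whitener: np.ndarray
    fitted_on: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        G = _as_spd(self.G, name="reference G")
        object.__setattr__(self, "G", G)
        W = np.asarray(self.whitener, dtype=float)
        if np.abs(W @ G @ W - np.eye(G.shape[0])).max() > 1e-8:
            raise ValueError("whitener does not satisfy W G W = I")

    @classmethod
    def fit(
        cls,
        covs: list[ConnectivityMatrix],
        tol: float = 1e-7,
        max_iter: int = 50,
    ) -> "TangentReference":
        if not covs:
            raise ValueError("need at least one covariance to fit the reference")
        G = geometric_mean([c.values for c in covs], tol=tol, max_iter=max_iter)
        return cls(
            G=G,
            whitener=_spd_power(G, -0.5),
            fitted_on=tuple(c.subject_id for c in covs),
        )

    @property
    def n_parcels(self) -> int:
        return self.G.shape[0]


def tangent_embed(cov: ConnectivityMatrix, ref: TangentReference) -> ConnectivityMatrix:
    """Project an SPD covariance to the tangent space at the reference.

    Returns ``logm(G^{-1/2} C G^{-1/2})``; the zero matrix iff ``C == G``.
    """
    if cov.n_parcels != ref.n_parcels:
        raise ValueError(
            f"dimension mismatch: covariance is {cov.n_parcels}, reference is {ref.n_parcels}"
        )
    A = _as_spd(cov.values, name="covariance")
    W = ref.whitener
    T = _sym_logm(W @ A @ W)
    return ConnectivityMatrix(subject_id=cov.subject_id, values=T, kind="tangent")


def tangent_to_covariance(tan: ConnectivityMatrix, ref: TangentReference) -> ConnectivityMatrix:
    """Inverse of :func:`tangent_embed`: ``G^{1/2} expm(T) G^{1/2}``."""
    if tan.n_parcels != ref.n_parcels:
        raise ValueError("dimension mismatch between tangent matrix and reference")
    G_half = _spd_power(ref.G, 0.5)
    C = G_half @ _sym_expm(tan.values) @ G_half
    return ConnectivityMatrix(subject_id=tan.subject_id, values=C, kind="covariance")


def average_matrices(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of a subject's condition matrices.

    Used both to collapse task conditions into one matrix per task and to
    collapse task matrices into a single task-general matrix per subject.
    """
    if not mats:
        raise ValueError("cannot average an empty list of matrices")
    sid = mats[0].subject_id
    shape = mats[0].values.shape
    for m in mats[1:]:
        if m.subject_id != sid:
            raise ValueError(
                f"refusing to average across subjects ({sid!r} vs {m.subject_id!r})"
            )
        if m.values.shape != shape:
            raise ValueError("matrices to average must share a shape")
    mean = sum(m.values for m in mats) / len(mats)
    return ConnectivityMatrix(subject_id=sid, values=mean, kind="average")


def contrast_matrices(
    specific: ConnectivityMatrix, general: ConnectivityMatrix
) -> ConnectivityMatrix:
    """Condition contrast: specific minus general (e.g., 2-back minus 0-back)."""
    if specific.subject_id != general.subject_id:
        raise ValueError("contrast requires matrices of the same subject")
    if specific.values.shape != general.values.shape:
        raise ValueError("contrast requires matrices of the same shape")
    return ConnectivityMatrix(
        subject_id=specific.subject_id,
        values=specific.values - general.values,
        kind="contrast",
    )
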