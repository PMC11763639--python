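"""Spatial-pattern distances on covariance matrices.

Two dissimilarities between EEG windows are defined through their SCMs:

* **sensor space** — the largest generalized eigenvalue λmax of (Ci, Cj),
  i.e. the maximal variance ratio attainable by a spatial filter (the
  common-spatial-pattern objective). It equals 1 iff the SCMs coincide and
  is symmetrized here as max(λmax(Ci,Cj), λmax(Cj,Ci)).
* **source space** — the affine-invariant Riemannian (geodesic) distance
  δ_R(Ci,Cj) = ‖logm(Ci^{-1/2} Cj Ci^{-1/2})‖_F on the SPD manifold, which
  is invariant to any invertible linear mixing of the underlying sources.

The Fréchet (geometric) mean and the logarithm map onto its tangent space
complete the toolbox. Matrix functions go through symmetric
eigendecompositions with a small eigenvalue floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "DistanceMatrix",
    "FrechetMeanError",
    "sensor_distance",
    "riemannian_distance",
    "frechet_mean",
    "log_map",
    "exp_map",
    "pairwise_matrix",
    "pairwise_both",
    "tangent_vectors",
    "random_spd",
]

_EIG_FLOOR = 1e-12


@dataclass
class DistanceMatrix:
    """m×m pairwise dissimilarities between windows.

    ``kind='sensor'`` holds symmetrized generalized-eigenvalue ratios
    (unit diagonal); ``kind='source'`` holds Riemannian distances (zero
    diagonal).
    """

    values: np.ndarray
    kind: str                     # 'sensor' | 'source'
    symmetrized: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("sensor", "source"):
            raise ValueError("kind must be 'sensor' or 'source'")

    @property
    def m(self) -> int:
        return self.values.shape[0]


class FrechetMeanError(RuntimeError):
    """Karcher flow failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


def _check_spd_shape(*mats: np.ndarray) -> None:
    shape = mats[0].shape
    for M in mats:
        if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape != shape:
            raise ValueError("inputs must be square matrices of a common size")


def _eigh_floor(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched symmetric eigendecomposition with the eigenvalue floor."""
    w, V = np.linalg.eigh(C)
    return np.maximum(w, _EIG_FLOOR), V


def _matfun(C: np.ndarray, fn, floor: float | None = None) -> np.ndarray:
    """Apply a scalar function to the spectrum of (a batch of) symmetric matrices.

    ``floor`` clamps eigenvalues from below — required for log/sqrt of SPD
    inputs, and must stay off for functions of indefinite tangent matrices.
    """
    w, V = np.linalg.eigh(C)
    if floor is not None:
        w = np.maximum(w, floor)
    return (V * fn(w)[..., None, :]) @ np.swapaxes(V, -1, -2)


def _sym(C: np.ndarray) -> np.ndarray:
    return 0.5 * (C + np.swapaxes(C, -1, -2))


def random_spd(n: int, rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    """A generic well-conditioned SPD matrix (for tests and demos)."""
    A = rng.standard_normal((n, 2 * n))
    return scale * (A @ A.T / (2 * n) + 0.1 * np.eye(n))


def sensor_distance(Ci: np.ndarray, Cj: np.ndarray, symmetrize: bool = True) -> float:
    """Largest generalized eigenvalue of Ci relative to Cj (≥ 1 symmetrized).

    Solves Ci·w = λ·Cj·w; the raw value is λmax, which is asymmetric in
    its arguments. With ``symmetrize`` (default) the result is
    max(λmax(Ci,Cj), λmax(Cj,Ci)) ≥ 1, equal to 1 iff Ci = Cj.
    """
    _check_spd_shape(Ci, Cj)
    lam = scipy.linalg.eigh(Ci, Cj, eigvals_only=True)
    if symmetrize:
        return float(max(lam[-1], 1.0 / lam[0]))
    return float(lam[-1])


def riemannian_distance(Ci: np.ndarray, Cj: np.ndarray) -> float:
    """Affine-invariant geodesic distance sqrt(Σ_e log² λ_e).

    λ_e are the eigenvalues of Ci^{-1/2} Cj Ci^{-1/2}, equivalently the
    generalized eigenvalues of (Cj, Ci).
    """
    _check_spd_shape(Ci, Cj)
    lam = scipy.linalg.eigh(Cj, Ci, eigvals_only=True)
    lam = np.maximum(lam, _EIG_FLOOR)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def log_map(E: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Tangent-space image of C at base point E:
    Log_E(C) = E^{1/2} logm(E^{-1/2} C E^{-1/2}) E^{1/2}."""
    _check_spd_shape(E, C)
    w, V = _eigh_floor(E)
    sq = (V * np.sqrt(w)) @ V.T
    isq = (V * (1.0 / np.sqrt(w))) @ V.T
    inner = _matfun(_sym(isq @ C @ isq), np.log, floor=_EIG_FLOOR)
    return _sym(sq @ inner @ sq)


def exp_map(E: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Inverse of :func:`log_map`: Exp_E(S) = E^{1/2} expm(E^{-1/2} S E^{-1/2}) E^{1/2}."""
    _check_spd_shape(E, S)
    w, V = _eigh_floor(E)
    sq = (V * np.sqrt(w)) @ V.T
    isq = (V * (1.0 / np.sqrt(w))) @ V.T
    inner = _matfun(_sym(isq @ S @ isq), np.exp)
    return _sym(sq @ inner @ sq)


def frechet_mean(mats: np.ndarray, tol: float = 1e-6, max_iter: int = 50) -> np.ndarray:
    """Fréchet/Karcher mean of a set of SPD matrices.

    Karcher fixed-point iteration starting at the arithmetic mean:
    E ← E^{1/2} expm( ν · mean_i logm(E^{-1/2} C_i E^{-1/2}) ) E^{1/2},
    stopping when the mean tangent vector's Frobenius norm (in whitened
    coordinates) drops to ``tol``. The step size ν starts at 1 and halves
    whenever the gradient norm fails to decrease, which keeps the flow
    stable on widely spread sets.
    """
    C = np.asarray(mats, dtype=float)
    if C.ndim == 2:
        C = C[None]
    if C.shape[0] == 0:
        raise ValueError("need a nonempty set of matrices")
    if C.shape[0] == 1:
        return C[0].copy()
    E = C.mean(axis=0)
    nu = 1.0
    prev_err = np.inf
    for _ in range(max_iter):
        w, V = _eigh_floor(E)
        sq = (V * np.sqrt(w)) @ V.T
        isq = (V * (1.0 / np.sqrt(w))) @ V.T
        inner = _sym(isq @ C @ isq)                 # batch (m, n, n)
        T = _matfun(inner, np.log, floor=_EIG_FLOOR).mean(axis=0)
        err = np.linalg.norm(T, "fro")
        if err <= tol:
            return _sym(E)
        if err >= prev_err:
            nu *= 0.5
        prev_err = err
        E = _sym(sq @ _matfun(_sym(nu * T), np.exp) @ sq)
    raise FrechetMeanError(
        f"Karcher flow did not reach tol={tol:g} in {max_iter} iterations "
        f"(last gradient norm {err:.3e})", last_iterate=_sym(E))


def _pairwise_generalized_eigs(mats: np.ndarray, chunk: int = 20000):
    """Yield (i, j, eigs) for all pairs i<j, eigs of Ci^{-1/2} Cj Ci^{-1/2}.

    One batched pass serves both distances: δ_R = sqrt(Σ log² λ) and the
    symmetrized sensor ratio max(λmax, 1/λmin) (the generalized eigenvalues
    of (Ci, Cj) are the reciprocals of those of (Cj, Ci)).
    """
    C = np.asarray(mats, dtype=float)
    m = C.shape[0]
    w, V = _eigh_floor(C)
    isq = (V * (1.0 / np.sqrt(w))[..., None, :]) @ np.swapaxes(V, -1, -2)
    ii, jj = np.triu_indices(m, k=1)
    for lo in range(0, len(ii), chunk):
        i = ii[lo:lo + chunk]
        j = jj[lo:lo + chunk]
        W = _sym(isq[i] @ C[j] @ isq[i])
        lam = np.maximum(np.linalg.eigvalsh(W), _EIG_FLOOR)
        yield i, j, lam


def pairwise_matrix(covset, kind: str) -> DistanceMatrix:
    """All-pairs distance matrix of a covariance set (or (m,n,n) array)."""
    mats = getattr(covset, "matrices", covset)
    mats = np.asarray(mats, dtype=float)
    m = mats.shape[0]
    if m < 2:
        raise ValueError("need at least 2 matrices")
    if kind == "sensor":
        D = np.ones((m, m))
    elif kind == "source":
        D = np.zeros((m, m))
    else:
        raise ValueError("kind must be 'sensor' or 'source'")
    for i, j, lam in _pairwise_generalized_eigs(mats):
        if kind == "source":
            vals = np.sqrt(np.sum(np.log(lam) ** 2, axis=-1))
        else:
            vals = np.maximum(lam[:, -1], 1.0 / lam[:, 0])
        D[i, j] = vals
        D[j, i] = vals
    return DistanceMatrix(values=D, kind=kind, symmetrized=True)


def pairwise_both(covset) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Sensor and source distance matrices from a single batched pass."""
    mats = getattr(covset, "matrices", covset)
    mats = np.asarray(mats, dtype=float)
    m = mats.shape[0]
    if m < 2:
        raise ValueError("need at least 2 matrices")
    Dsen = np.ones((m, m))
    Dsrc = np.zeros((m, m))
    for i, j, lam in _pairwise_generalized_eigs(mats):
        src = np.sqrt(np.sum(np.log(lam) ** 2, axis=-1))
        sen = np.maximum(lam[:, -1], 1.0 / lam[:, 0])
        Dsrc[i, j] = src
        Dsrc[j, i] = src
        Dsen[i, j] = sen
        Dsen[j, i] = sen
    return (DistanceMatrix(Dsen, "sensor", True), DistanceMatrix(Dsrc, "source", True))


def tangent_vectors(mats: np.ndarray, base: np.ndarray | None = None,
                    weighted: bool = True) -> np.ndarray:
    """Map SPD matrices to tangent vectors at ``base`` (default: their Fréchet mean).

    Returns an (m, n(n+1)/2) array of upper-triangle vectorizations. With
    ``weighted`` the off-diagonal entries are scaled by √2 so Euclidean
    inner products of the vectors equal Frobenius inner products of the
    tangent matrices.
    """
    C = np.asarray(mats, dtype=float)
    if base is None:
        base = frechet_mean(C)
    w, V = _eigh_floor(base)
    sq = (V * np.sqrt(w)) @ V.T
    isq = (V * (1.0 / np.sqrt(w))) @ V.T
    inner = _matfun(_sym(isq @ C @ isq), np.log, floor=_EIG_FLOOR)
    logs = _sym(sq @ inner @ sq)
    n = C.shape[-1]
    iu = np.triu_indices(n)
    vecs = logs[:, iu[0], iu[1]]
    if weighted:
        scale = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
        vecs = vecs * scale
    return vecs
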