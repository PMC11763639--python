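"""Feature fusion: classical MDS of the distance matrices plus log variances.

Each window contributes three n-dimensional blocks — the log of its SCM
diagonal (per-channel log variance), MDS coordinates of the sensor-space
distance matrix, and MDS coordinates of the source-space (Riemannian)
distance matrix. Blocks are z-standardized column-wise and concatenated
into an m × 3n feature matrix.

The sensor-space matrix has a unit diagonal (ratios ≥ 1), so it is passed
through an elementwise log before MDS: log(1) = 0 gives the zero diagonal
classical MDS requires, and the log scale is commensurate with the
Riemannian distance (which is itself a norm of log eigenvalue ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import DistanceMatrix
from .segment import CovarianceSet

__all__ = ["FeatureMatrix", "classical_mds", "build_features"]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """m × 3n fused, block-standardized feature vectors."""

    values: np.ndarray
    block_slices: dict[str, slice]            # 'logdiag' | 'mds_sensor' | 'mds_source'
    block_means: dict[str, np.ndarray]
    block_sds: dict[str, np.ndarray]

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def classical_mds(D: np.ndarray, dim: int, tol: float = 1e-8) -> np.ndarray:
    """Torgerson classical scaling of a symmetric zero-diagonal dissimilarity.

    Double-centers the squared dissimilarities, B = −½ J (D∘D) J, keeps the
    top ``dim`` eigenpairs, clips negative eigenvalues to zero (with a
    warning: the input was not Euclidean-embeddable), and returns
    coordinates eigenvector·sqrt(eigenvalue), columns ordered by decreasing
    eigenvalue.
    """
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    if D.ndim != 2 or D.shape[1] != m:
        raise ValueError("D must be square")
    if not 1 <= dim <= m - 1:
        raise ValueError(f"dim must be in [1, m-1={m - 1}]")
    if np.max(np.abs(D - D.T)) > tol * max(1.0, np.max(np.abs(D))):
        raise ValueError("D must be symmetric")
    if np.max(np.abs(np.diag(D))) > tol * max(1.0, np.max(np.abs(D))):
        raise ValueError("D must have a zero diagonal")
    D2 = (0.5 * (D + D.T)) ** 2
    B = -0.5 * (D2 - D2.mean(axis=0, keepdims=True)
                - D2.mean(axis=1, keepdims=True) + D2.mean())
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    w_top = w[order]
    if np.any(w_top < -tol * max(1.0, abs(w[-1]))):
        logger.warning("classical MDS: clipping %d negative eigenvalues to zero",
                       int(np.sum(w_top < 0)))
    w_top = np.clip(w_top, 0.0, None)
    return V[:, order] * np.sqrt(w_top)[None, :]


def _zscore(block: np.ndarray, tol: float = 1e-12
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-score; (numerically) zero-variance columns map to all-zeros."""
    mu = block.mean(axis=0)
    sd = block.std(axis=0)
    live = sd > tol
    out = np.where(live, (block - mu) / np.where(live, sd, 1.0), 0.0)
    return out, mu, sd


def build_features(covset: CovarianceSet, D_sensor: DistanceMatrix,
                   D_source: DistanceMatrix) -> FeatureMatrix:
    """Fuse log variances and the two MDS embeddings into m × 3n features."""
    C = covset.matrices
    m, n = C.shape[0], C.shape[1]
    if D_sensor.kind != "sensor" or D_source.kind != "source":
        raise ValueError("distance matrices must be (sensor, source), in that order")
    if D_sensor.m != m or D_source.m != m:
        raise ValueError("distance matrices must match the covariance set size")
    diags = np.diagonal(C, axis1=1, axis2=2)
    if np.any(diags <= 0.0):
        raise ValueError("SCM diagonals must be positive for the log transform")
    blocks = {
        "logdiag": np.log(diags),
        "mds_sensor": classical_mds(np.log(D_sensor.values), n),
        "mds_source": classical_mds(D_source.values, n),
    }
    std_blocks, means, sds, slices = [], {}, {}, {}
    col = 0
    for name, block in blocks.items():
        z, mu, sd = _zscore(block)
        std_blocks.append(z)
        means[name], sds[name] = mu, sd
        slices[name] = slice(col, col + n)
        col += n
    V = np.hstack(std_blocks)
    return FeatureMatrix(values=V, block_slices=slices, block_means=means, block_sds=sds)
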