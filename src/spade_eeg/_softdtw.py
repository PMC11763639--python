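"""Soft dynamic time warping primitives (numba kernels).

Implements the smoothed-minimum DTW value, its gradient with respect to
the pairwise cost matrix (the alignment expectation E), and helpers for
multivariate series with squared-Euclidean ground cost. The exponent in
the backward pass is always ≤ 0 (soft-min is a lower bound on each
predecessor), so the recursions are overflow-safe.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sdtw_value", "sdtw_value_grad", "cost_matrix", "sdtw_divergence"]


@njit(cache=True)
def _forward(D: np.ndarray, gamma: float) -> np.ndarray:
    m, n = D.shape
    R = np.full((m + 1, n + 1), np.inf)
    R[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            r0 = -R[i - 1, j - 1] / gamma
            r1 = -R[i - 1, j] / gamma
            r2 = -R[i, j - 1] / gamma
            rmax = max(r0, max(r1, r2))
            softmin = -gamma * (np.log(np.exp(r0 - rmax) + np.exp(r1 - rmax)
                                       + np.exp(r2 - rmax)) + rmax)
            R[i, j] = D[i - 1, j - 1] + softmin
    return R


@njit(cache=True)
def _backward(D: np.ndarray, R: np.ndarray, gamma: float) -> np.ndarray:
    m, n = D.shape
    E = np.zeros((m + 2, n + 2))
    E[m, n] = 1.0
    for j in range(n, 0, -1):
        for i in range(m, 0, -1):
            if i == m and j == n:
                continue
            acc = 0.0
            if i + 1 <= m:
                acc += E[i + 1, j] * np.exp((R[i + 1, j] - D[i, j - 1] - R[i, j]) / gamma)
            if j + 1 <= n:
                acc += E[i, j + 1] * np.exp((R[i, j + 1] - D[i - 1, j] - R[i, j]) / gamma)
            if i + 1 <= m and j + 1 <= n:
                acc += E[i + 1, j + 1] * np.exp((R[i + 1, j + 1] - D[i, j] - R[i, j]) / gamma)
            E[i, j] = acc
    return E[1:m + 1, 1:n + 1]


def cost_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared-Euclidean cost between two (time × dims) series."""
    d2 = (np.sum(X ** 2, axis=1)[:, None] + np.sum(Y ** 2, axis=1)[None, :]
          - 2.0 * X @ Y.T)
    return np.maximum(d2, 0.0)


def sdtw_value(X: np.ndarray, Y: np.ndarray, gamma: float = 1.0) -> float:
    """Soft-DTW value between two (time × dims) series."""
    R = _forward(cost_matrix(X, Y), gamma)
    return float(R[-1, -1])


def sdtw_value_grad(X: np.ndarray, Y: np.ndarray, gamma: float = 1.0
                    ) -> tuple[float, np.ndarray]:
    """Soft-DTW value and its gradient with respect to X.

    The gradient chains the alignment expectation E through the
    squared-Euclidean cost: ∂/∂x_i = 2 Σ_j E_ij (x_i − y_j).
    """
    D = cost_matrix(X, Y)
    R = _forward(D, gamma)
    E = _backward(D, R, gamma)
    grad = 2.0 * (X * E.sum(axis=1)[:, None] - E @ Y)
    return float(R[-1, -1]), grad


def sdtw_divergence(X: np.ndarray, Y: np.ndarray, gamma: float = 1.0,
                    self_x: float | None = None, self_y: float | None = None) -> float:
    """Debiased soft-DTW: sdtw(X,Y) − ½ sdtw(X,X) − ½ sdtw(Y,Y); zero at X = Y."""
    if self_x is None:
        self_x = sdtw_value(X, X, gamma)
    if self_y is None:
        self_y = sdtw_value(Y, Y, gamma)
    return sdtw_value(X, Y, gamma) - 0.5 * (self_x + self_y)
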