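"""Baseline microstate clustering algorithms for the comparison study.

Six baselines span the common families: GFP-peak topography clustering
(the classical resting-state microstate approach), a Gaussian mixture on
raw samples, soft-DTW K-means on windows, and three SCM-based variants —
flattened-vector K-means, autoencoder-latent K-means, and tangent-space
K-means at the Fréchet mean. Per-segment baselines consume exactly the
same window/covariance sets as the main pipeline so comparisons are fair.

All labels are returned 1-based, per-sample or per-segment as noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from ._softdtw import cost_matrix, sdtw_value, sdtw_value_grad, _forward
from .dec import EncoderSpec, pretrain_autoencoder
from .geometry import tangent_vectors
from .segment import CovarianceSet, EEGRecord, SegmentSet

__all__ = [
    "BaselineResult",
    "gfp_microstates",
    "gmm_cluster",
    "softdtw_cluster",
    "scm_vector_kmeans",
    "ae_kmeans",
    "tangent_kmeans",
]


@dataclass
class BaselineResult:
    algorithm_id: int                       # 1..6
    granularity: str                        # 'per-sample' | 'per-segment'
    labels: np.ndarray                      # 1-based
    auxiliary: dict = field(default_factory=dict)


def _nearest_anchor_labels(anchors: np.ndarray, anchor_labels: np.ndarray,
                           T: int) -> np.ndarray:
    """Label every sample by its temporally nearest anchor (ties → earlier)."""
    mids = (anchors[:-1] + anchors[1:]) / 2.0
    idx = np.searchsorted(mids, np.arange(T), side="left")
    return anchor_labels[idx]


def gfp_microstates(record: EEGRecord, s: int, seed: int = 0,
                    normalize: bool = False) -> np.ndarray:
    """Algorithm 1: K-means on topographies at GFP peaks, per-sample labels.

    GFP(t) is the spatial standard deviation across channels; strict local
    maxima anchor the clustering and every sample inherits the cluster of
    its temporally nearest peak. ``normalize`` rescales peak maps to unit
    GFP before K-means (polarity stays significant either way).
    """
    X = record.data
    gfp = X.std(axis=0)
    interior = gfp[1:-1]
    peaks = np.where((interior > gfp[:-2]) & (interior > gfp[2:]))[0] + 1
    if len(peaks) < s:
        raise ValueError(f"only {len(peaks)} strict GFP maxima; need at least s={s}")
    maps = X[:, peaks].T
    if normalize:
        maps = maps / gfp[peaks][:, None]
    km = KMeans(n_clusters=s, n_init=10, random_state=seed % (2 ** 31)).fit(maps)
    return _nearest_anchor_labels(peaks, km.labels_ + 1, record.n_samples)


def gmm_cluster(record: EEGRecord, s: int = 5, seed: int = 0,
                covariance_type: str = "tied") -> np.ndarray:
    """Algorithm 2: Gaussian mixture on samples viewed as n-D points.

    The default shares one covariance across components (``tied``), so
    components separate by mean topography — the convention under which
    this sample-level baseline behaves as reported on oscillatory,
    near-zero-mean data (per-component ``full`` covariance would instead
    pick up the states' spatial covariance structure itself).
    """
    X = record.data.T
    if X.shape[0] <= s:
        raise ValueError("need more samples than mixture components")
    for reg in (1e-6, 1e-3):
        try:
            gm = GaussianMixture(n_components=s, covariance_type=covariance_type,
                                 random_state=seed % (2 ** 31), reg_covar=reg)
            labels = gm.fit_predict(X)
            return labels + 1
        except (ValueError, np.linalg.LinAlgError):
            continue
    raise RuntimeError("GMM fit failed even with increased covariance regularization")


def _sdtw_barycenter(members: np.ndarray, init: np.ndarray, gamma: float,
                     maxfun: int = 10) -> np.ndarray:
    """L-BFGS refinement of a soft-DTW barycenter from ``init``."""
    shape = init.shape

    def fg(flat: np.ndarray):
        b = flat.reshape(shape)
        total, grad = 0.0, np.zeros(shape)
        for x in members:
            v, g = sdtw_value_grad(b, x, gamma)
            total += v
            grad += g
        return total / len(members), (grad / len(members)).ravel()

    res = scipy.optimize.minimize(fg, init.ravel(), jac=True, method="L-BFGS-B",
                                  options={"maxfun": maxfun, "maxiter": maxfun})
    return res.x.reshape(shape)


def softdtw_cluster(segments: SegmentSet, s: int = 5, gamma_smooth: float = 1.0,
                    seed: int = 0, max_iter: int = 4,
                    barycenter_maxfun: int = 4,
                    barycenter_sample: int = 48,
                    n_candidates: int | None = None) -> np.ndarray:
    """Algorithm 3: K-means-style clustering of windows under soft-DTW.

    Windows are treated as multivariate series (time × channels); cluster
    assignment uses the debiased soft-DTW divergence and barycenters are
    refined by gradient-based minimization of the mean soft-DTW cost,
    warm-started from the cluster's Euclidean mean.

    Each barycenter update works on a random subsample of at most
    ``barycenter_sample`` members — an unbiased estimate of the cluster's
    mean alignment cost that keeps the quadratic dynamic programs
    affordable at step-1 window counts. Setting ``n_candidates`` below the
    cluster count additionally restricts each assignment to the centers
    nearest in plain Euclidean distance (an optional approximation, off by
    default). Returns per-segment labels.
    """
    X = segments.segments.transpose(0, 2, 1)  # (m, t, n)
    m = X.shape[0]
    if m < s:
        raise ValueError("need at least s segments")
    n_candidates = s if n_candidates is None else min(n_candidates, s)
    rng = np.random.default_rng(seed)
    self_vals = np.array([sdtw_value(x, x, gamma_smooth) for x in X])
    centers = X[rng.choice(m, size=s, replace=False)].copy()
    labels = np.full(m, -1)
    Xf = X.reshape(m, -1)
    for _ in range(max_iter):
        center_self = np.array([sdtw_value(b, b, gamma_smooth) for b in centers])
        eu = ((Xf[:, None, :] - centers.reshape(s, -1)[None]) ** 2).sum(-1)
        cand = np.argsort(eu, axis=1)[:, :n_candidates]
        div = np.full((m, s), np.inf)
        for i in range(m):
            for j in cand[i]:
                val = float(_forward(cost_matrix(X[i], centers[j]),
                                     gamma_smooth)[-1, -1])
                div[i, j] = val - 0.5 * (self_vals[i] + center_self[j])
        new_labels = div.argmin(axis=1)
        for j in np.setdiff1d(np.arange(s), new_labels):
            far = int(np.argmax(np.min(div, axis=1)))
            centers[j] = X[far].copy()
            new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(s):
            members = X[labels == j]
            if len(members) > barycenter_sample:
                members = members[rng.choice(len(members), barycenter_sample,
                                             replace=False)]
            init = members.mean(axis=0)
            centers[j] = _sdtw_barycenter(members, init, gamma_smooth,
                                          maxfun=barycenter_maxfun)
    return labels + 1


def vectorize_scm(covset: CovarianceSet) -> np.ndarray:
    """Flatten each SCM to its n(n+1)/2 upper-triangle entries (with diagonal)."""
    C = covset.matrices
    iu = np.triu_indices(C.shape[1])
    return C[:, iu[0], iu[1]]


def scm_vector_kmeans(covset: CovarianceSet, s: int = 5, seed: int = 0) -> np.ndarray:
    """Algorithm 4: K-means on flattened SCM vectors (10 restarts)."""
    V = vectorize_scm(covset)
    if V.shape[0] < s:
        raise ValueError("need at least s segments")
    km = KMeans(n_clusters=s, n_init=10, random_state=seed % (2 ** 31)).fit(V)
    return km.labels_ + 1


def ae_kmeans(covset: CovarianceSet, spec: EncoderSpec, s: int = 5,
              seed: int = 0) -> np.ndarray:
    """Algorithm 5: K-means in the latent space of an autoencoder on SCM vectors.

    Vectors are column-standardized before the autoencoder (zero-variance
    columns pass through unscaled).
    """
    V = vectorize_scm(covset)
    mu, sd = V.mean(axis=0), V.std(axis=0)
    V = (V - mu) / np.where(sd > 0, sd, 1.0)
    import dataclasses
    ae_spec = dataclasses.replace(spec, seed=seed)
    _, Z = pretrain_autoencoder(V, ae_spec)
    km = KMeans(n_clusters=s, n_init=10, random_state=seed % (2 ** 31)).fit(Z)
    return km.labels_ + 1


def tangent_kmeans(covset: CovarianceSet, s: int = 5, seed: int = 0,
                   weighted: bool = True) -> np.ndarray:
    """Algorithm 6: K-means in the tangent space at the Fréchet mean of all SCMs.

    ``weighted`` applies √2 scaling to off-diagonal entries so Euclidean
    K-means respects the Frobenius metric on tangent matrices; disable for
    plain upper-triangle flattening.
    """
    vecs = tangent_vectors(covset.matrices, weighted=weighted)
    if vecs.shape[0] < s:
        raise ValueError("need at least s segments")
    km = KMeans(n_clusters=s, n_init=10, random_state=seed % (2 ** 31)).fit(vecs)
    return km.labels_ + 1
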