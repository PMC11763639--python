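"""Statistical validation of a clustering via Riemannian distance sampling.

For every unordered pair of clusters, two sampling distributions of
pairwise Riemannian distances are drawn from the precomputed distance
matrix: within-cluster distances (pooled equally over the two clusters)
and cross-cluster distances. A clustering is supported when the
within-cluster distribution is significantly smaller — a one-tailed Welch
t-test per pair, Benjamini–Hochberg FDR across pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .geometry import DistanceMatrix

__all__ = ["DistanceSamples", "sample_distances", "intra_inter_test", "validation_table"]

logger = logging.getLogger(__name__)


@dataclass
class DistanceSamples:
    """Sampled intra/inter distances and test results for one cluster pair."""

    cluster_pair: tuple[int, int]
    intra: np.ndarray
    inter: np.ndarray
    t_statistic: float = np.nan
    p_value: float = np.nan
    p_adjusted: float = np.nan

    @property
    def intra_mean(self) -> float:
        return float(self.intra.mean())

    @property
    def intra_sd(self) -> float:
        return float(self.intra.std(ddof=1))

    @property
    def inter_mean(self) -> float:
        return float(self.inter.mean())

    @property
    def inter_sd(self) -> float:
        return float(self.inter.std(ddof=1))


def _within_pairs(members: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k random unordered pairs of distinct members, with replacement across draws."""
    i = rng.integers(0, len(members), size=k)
    j = rng.integers(0, len(members) - 1, size=k)
    j = np.where(j >= i, j + 1, j)  # distinct second index, uniform
    return np.stack([members[i], members[j]], axis=1)


def sample_distances(D_source: DistanceMatrix | np.ndarray, labels,
                     n_pairs: int = 1000, seed: int = 0,
                     pool_intra: bool = True) -> list[DistanceSamples]:
    """Sample intra- and inter-cluster distance distributions per cluster pair.

    For each unordered pair (a, b): the intra distribution holds ``n_pairs``
    within-cluster distances (split evenly between a and b when
    ``pool_intra``, else drawn from a alone), and the inter distribution
    holds ``n_pairs`` distances between a random member of a and one of b.
    Pairs involving a singleton cluster are skipped with a warning.
    """
    D = getattr(D_source, "values", D_source)
    labels = np.asarray(labels)
    if len(labels) != D.shape[0]:
        raise ValueError("labels must match the distance matrix size")
    rng = np.random.default_rng(seed)
    ids = np.unique(labels)
    out: list[DistanceSamples] = []
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = int(ids[ai]), int(ids[bi])
            mem_a = np.where(labels == ids[ai])[0]
            mem_b = np.where(labels == ids[bi])[0]
            if len(mem_a) < 2 or len(mem_b) < 2:
                logger.warning("cluster pair (%s, %s): singleton cluster, skipped", a, b)
                continue
            if pool_intra:
                ka = n_pairs // 2
                pairs = np.vstack([_within_pairs(mem_a, ka, rng),
                                   _within_pairs(mem_b, n_pairs - ka, rng)])
            else:
                pairs = _within_pairs(mem_a, n_pairs, rng)
            intra = D[pairs[:, 0], pairs[:, 1]]
            ia = rng.integers(0, len(mem_a), size=n_pairs)
            ib = rng.integers(0, len(mem_b), size=n_pairs)
            inter = D[mem_a[ia], mem_b[ib]]
            out.append(DistanceSamples(cluster_pair=(a, b), intra=intra.copy(),
                                       inter=inter.copy()))
    return out


def intra_inter_test(samples: list[DistanceSamples],
                     alpha: float = 0.05) -> list[DistanceSamples]:
    """Welch one-tailed t-tests (H1: mean intra < mean inter) with BH-FDR.

    Mutates and returns the sample list. Degenerate zero-variance identical
    distributions get the p = 0.5 convention.
    """
    for ds in samples:
        if len(ds.intra) == 0 or len(ds.inter) == 0:
            raise ValueError("empty distance distribution")
        if np.ptp(ds.intra) == 0 and np.ptp(ds.inter) == 0 and \
                ds.intra[0] == ds.inter[0]:
            logger.warning("cluster pair %s: identical degenerate distributions, p=0.5",
                           ds.cluster_pair)
            ds.t_statistic, ds.p_value = 0.0, 0.5
            continue
        res = scipy.stats.ttest_ind(ds.intra, ds.inter, equal_var=False,
                                    alternative="less")
        ds.t_statistic = float(res.statistic)
        ds.p_value = float(res.pvalue)
    if samples:
        adj = multipletests([ds.p_value for ds in samples], alpha=alpha,
                            method="fdr_bh")[1]
        for ds, p in zip(samples, adj):
            ds.p_adjusted = float(p)
    return samples


def validation_table(samples: list[DistanceSamples]) -> pd.DataFrame:
    """Tidy per-pair table: means/SDs of both distributions, t, p, adjusted p."""
    rows = [{
        "cluster_a": ds.cluster_pair[0],
        "cluster_b": ds.cluster_pair[1],
        "intra_mean": ds.intra_mean,
        "intra_sd": ds.intra_sd,
        "inter_mean": ds.inter_mean,
        "inter_sd": ds.inter_sd,
        "t": ds.t_statistic,
        "p": ds.p_value,
        "p_adj": ds.p_adjusted,
    } for ds in samples]
    return pd.DataFrame(rows)
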