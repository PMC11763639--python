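"""Clustering evaluation metrics and the cross-algorithm comparison protocol.

Four external metrics score a clustering against ground truth — Adjusted
Rand Index, Normalized Mutual Information (geometric-mean normalization),
Purity, and pair-counting F1 — and one internal metric, the silhouette,
scores cohesion/separation from a precomputed Riemannian distance matrix.
Algorithms are compared across datasets with paired tests (t-test when all
score vectors pass Shapiro–Wilk normality, Wilcoxon signed-rank otherwise)
under Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score, silhouette_score
from sklearn.metrics.cluster import contingency_matrix, pair_confusion_matrix
from statsmodels.stats.multitest import multipletests

from .geometry import DistanceMatrix

__all__ = [
    "ari",
    "nmi",
    "purity",
    "pair_f1",
    "riemannian_silhouette",
    "score_labels",
    "ComparisonResult",
    "compare_algorithms",
    "METRIC_NAMES",
]

METRIC_NAMES = ("ARI", "NMI", "Purity", "F1", "Silhouette")


def _check_lengths(labels, truth) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape or labels.ndim != 1:
        raise ValueError("labels and truth must be 1-D arrays of equal length")
    return labels, truth


def ari(labels, truth) -> float:
    """Adjusted Rand Index: pair-counting agreement, chance-corrected.

    1 for identical partitions (including the single-cluster/single-cluster
    case), around 0 for random labelings, negative for worse than chance.
    """
    labels, truth = _check_lengths(labels, truth)
    return float(adjusted_rand_score(truth, labels))


def _partitions_identical(labels: np.ndarray, truth: np.ndarray) -> bool:
    """True when the two labelings induce the same grouping of indices."""
    _, a = np.unique(labels, return_inverse=True)
    _, b = np.unique(truth, return_inverse=True)
    # same grouping iff the joint relabeling is a bijection
    pairs = np.unique(np.stack([a, b], axis=1), axis=0)
    return len(pairs) == len(np.unique(a)) == len(np.unique(b))


def nmi(labels, truth) -> float:
    """Normalized Mutual Information, I(U,V)/sqrt(H(U)·H(V)).

    A zero-entropy partition (a single cluster) makes the normalizer
    vanish; that case is defined as 1 when the partitions are identical
    and 0 otherwise.
    """
    labels, truth = _check_lengths(labels, truth)
    if len(np.unique(labels)) == 1 or len(np.unique(truth)) == 1:
        return 1.0 if _partitions_identical(labels, truth) else 0.0
    return float(normalized_mutual_info_score(truth, labels, average_method="geometric"))


def purity(labels, truth) -> float:
    """Fraction of points in their cluster's majority class: (1/T) Σ_k max_j |r_k ∩ l_j|."""
    labels, truth = _check_lengths(labels, truth)
    cont = contingency_matrix(truth, labels)
    return float(cont.max(axis=0).sum() / len(labels))


def pair_f1(labels, truth) -> float:
    """Pair-counting F1: harmonic mean of precision and recall over same-cluster pairs."""
    labels, truth = _check_lengths(labels, truth)
    # pair_confusion_matrix counts ordered pairs: [[2TN, 2FP], [2FN, 2TP]]
    C = pair_confusion_matrix(truth, labels)
    tp, fp, fn = C[1, 1] / 2.0, C[0, 1] / 2.0, C[1, 0] / 2.0
    if tp + fp == 0 or tp + fn == 0 or tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return float(2.0 * p * r / (p + r))


def riemannian_silhouette(labels, D_source: DistanceMatrix | np.ndarray) -> float:
    """Mean silhouette (b−a)/max(a,b) from a precomputed distance matrix.

    Built for the source-space (Riemannian) distances between window SCMs
    but accepts any symmetric dissimilarity. Singleton clusters score 0.
    Raises on a single-cluster labeling, for which the score is undefined.
    """
    D = getattr(D_source, "values", D_source)
    labels = np.asarray(labels)
    if len(labels) != D.shape[0]:
        raise ValueError("labels must match the distance matrix size")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    return float(silhouette_score(D, labels, metric="precomputed"))


def score_labels(labels, truth, D: DistanceMatrix | np.ndarray | None = None,
                 silhouette_labels=None) -> dict[str, float]:
    """All five metrics for one clustering; silhouette only when D is given.

    ``silhouette_labels`` overrides the labeling scored by the silhouette
    (used when truth-based metrics are computed at a different granularity
    than the distance matrix).
    """
    out = {
        "ARI": ari(labels, truth),
        "NMI": nmi(labels, truth),
        "Purity": purity(labels, truth),
        "F1": pair_f1(labels, truth),
    }
    if D is not None:
        sl = labels if silhouette_labels is None else silhouette_labels
        try:
            out["Silhouette"] = riemannian_silhouette(sl, D)
        except ValueError:
            out["Silhouette"] = np.nan
    return out


@dataclass
class ComparisonResult:
    """Paired-test outcomes of baselines against a reference algorithm."""

    metric: str
    reference: str
    test_used: str                      # 'paired t' | 'wilcoxon'
    normality_p: dict[str, float]
    table: pd.DataFrame                 # algorithm, statistic, p, p_adj

    @property
    def all_significant(self) -> bool:
        return bool((self.table["p_adj"] < 0.05).all())


def compare_algorithms(scores: dict[str, np.ndarray], reference: str,
                       alpha: float = 0.05, metric: str = "") -> ComparisonResult:
    """Compare every algorithm's paired score vector against the reference.

    Shapiro–Wilk gates the test family: paired t-tests when every
    algorithm's scores look normal at ``alpha``, else Wilcoxon signed-rank
    (zero-difference pairs dropped per the standard convention; an
    all-zero difference vector yields p = 1). Benjamini–Hochberg FDR is
    applied across the comparisons of this metric.
    """
    if reference not in scores:
        raise ValueError(f"reference {reference!r} missing from scores")
    lengths = {len(v) for v in scores.values()}
    if len(lengths) != 1:
        raise ValueError("all score vectors must be paired (equal length)")
    normality = {}
    for name, vec in scores.items():
        v = np.asarray(vec, dtype=float)
        # Shapiro-Wilk needs variation; a constant vector is trivially non-normal
        normality[name] = float(scipy.stats.shapiro(v).pvalue) if np.ptp(v) > 0 else 0.0
    all_normal = all(p > alpha for p in normality.values())
    test_used = "paired t" if all_normal else "wilcoxon"
    ref = np.asarray(scores[reference], dtype=float)
    rows = []
    for name, vec in scores.items():
        if name == reference:
            continue
        v = np.asarray(vec, dtype=float)
        diff = ref - v
        if np.all(diff == 0):
            stat, p = 0.0, 1.0
        elif all_normal:
            res = scipy.stats.ttest_rel(ref, v)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = scipy.stats.wilcoxon(ref, v, zero_method="wilcox")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"algorithm": name, "statistic": stat, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["p_adj"] = []
    return ComparisonResult(metric=metric, reference=reference, test_used=test_used,
                            normality_p=normality, table=table)
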