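"""Evaluation metrics against brute-force oracles, and the comparison protocol."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spade_eeg.metrics import ari, compare_algorithms, nmi, pair_f1, purity, riemannian_silhouette


# ---------------------------------------------------------------- oracles

def _pair_counts(labels, truth):
    """Brute-force enumeration of all sample pairs."""
    tp = fp = fn = tn = 0
    n = len(labels)
    for i, j in itertools.combinations(range(n), 2):
        same_l = labels[i] == labels[j]
        same_t = truth[i] == truth[j]
        tp += same_l and same_t
        fp += same_l and not same_t
        fn += (not same_l) and same_t
        tn += (not same_l) and not same_t
    return tp, fp, fn, tn


def _ari_oracle(labels, truth):
    tp, fp, fn, tn = _pair_counts(labels, truth)
    total = tp + fp + fn + tn
    ri = (tp + tn) / total
    # expected and maximum index from the pair-counting formulation
    sum_l = tp + fp
    sum_t = tp + fn
    expected = sum_l * sum_t / total
    max_index = 0.5 * (sum_l + sum_t)
    if max_index == expected:
        return 1.0
    return (tp - expected) / (max_index - expected)


def _nmi_oracle(labels, truth):
    labels, truth = np.asarray(labels), np.asarray(truth)
    n = len(labels)
    ls, ts = np.unique(labels), np.unique(truth)
    if len(ls) == 1 or len(ts) == 1:
        raise ValueError("oracle needs non-degenerate partitions")
    mi = 0.0
    for a in ls:
        for b in ts:
            nij = np.sum((labels == a) & (truth == b))
            if nij:
                mi += nij / n * math.log(nij * n / (np.sum(labels == a)
                                                   * np.sum(truth == b)))
    hl = -sum(np.sum(labels == a) / n * math.log(np.sum(labels == a) / n) for a in ls)
    ht = -sum(np.sum(truth == b) / n * math.log(np.sum(truth == b) / n) for b in ts)
    return mi / math.sqrt(hl * ht)


def _silhouette_oracle(labels, D):
    labels = np.asarray(labels)
    vals = []
    for i in range(len(labels)):
        own = np.where(labels == labels[i])[0]
        own = own[own != i]
        if len(own) == 0:
            vals.append(0.0)
            continue
        a = D[i, own].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels)
                if c != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


# ---------------------------------------------------------------- tests

class TestARI:
    def test_identical_partitions(self):
        assert ari([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
        assert ari([3, 3, 3], [7, 7, 7]) == 1.0  # single cluster in both

    def test_hand_example_crossed_pairs(self):
        assert ari([1, 2, 1, 2], [1, 1, 2, 2]) == pytest.approx(-0.5)

    def test_relabeling_invariance(self):
        truth = [1, 1, 2, 2, 3]
        assert ari([1, 1, 2, 2, 3], truth) == ari([2, 2, 3, 3, 1], truth)

    @given(st.lists(st.integers(1, 3), min_size=3, max_size=6),
           st.lists(st.integers(1, 3), min_size=3, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_on_small_partitions(self, a, b):
        k = min(len(a), len(b))
        assert ari(a[:k], b[:k]) == pytest.approx(_ari_oracle(a[:k], b[:k]),
                                                  abs=1e-10)


class TestNMI:
    def test_identical_partitions(self):
        assert nmi([1, 2, 2, 3], [5, 6, 6, 7]) == pytest.approx(1.0)

    def test_hand_contingency_example(self):
        got = nmi([1, 1, 1, 2], [1, 1, 2, 2])
        assert got == pytest.approx(_nmi_oracle([1, 1, 1, 2], [1, 1, 2, 2]),
                                    abs=1e-10)

    def test_independent_partitions_near_zero(self, rng):
        # product of uniform marginals: MI -> 0 for large samples
        a = rng.integers(1, 4, size=20000)
        b = rng.integers(1, 4, size=20000)
        assert nmi(a, b) < 0.01

    def test_degenerate_single_cluster_conventions(self):
        assert nmi([1, 1, 1], [2, 2, 2]) == 1.0
        assert nmi([1, 1, 1], [1, 2, 3]) == 0.0

    @given(st.lists(st.integers(1, 3), min_size=4, max_size=6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_bruteforce(self, a):
        b = [1, 2, 1, 2, 1, 2][:len(a)]
        if len(set(a)) < 2:
            return
        assert nmi(a, b) == pytest.approx(_nmi_oracle(a, b), abs=1e-10)


class TestPurity:
    def test_direct_count_example(self):
        # clusters {a,a,b} and {b,b}: (2+2)/5
        assert purity([1, 1, 1, 2, 2], ["a", "a", "b", "b", "b"]) == \
            pytest.approx(0.8)

    def test_singleton_clusters_are_pure(self):
        assert purity([1, 2, 3, 4], [1, 1, 2, 2]) == 1.0

    def test_single_cluster_balanced_classes(self):
        assert purity([1, 1, 1, 1], [1, 1, 2, 2]) == 0.5


class TestPairF1:
    def test_identical_partitions(self):
        assert pair_f1([1, 1, 2], [1, 1, 2]) == 1.0

    def test_no_true_positive_pairs(self):
        assert pair_f1([1, 2, 1, 2], [1, 1, 2, 2]) == 0.0

    def test_hand_enumeration_example(self):
        # truth (1,1,1), labels (1,1,2): TP=1, FP=0, FN=2 -> P=1, R=1/3
        assert pair_f1([1, 1, 2], [1, 1, 1]) == pytest.approx(0.5)

    @given(st.lists(st.integers(1, 3), min_size=3, max_size=6),
           st.lists(st.integers(1, 3), min_size=3, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce(self, a, b):
        k = min(len(a), len(b))
        tp, fp, fn, _ = _pair_counts(a[:k], b[:k])
        if tp == 0:
            expected = 0.0
        else:
            p, r = tp / (tp + fp), tp / (tp + fn)
            expected = 2 * p * r / (p + r)
        assert pair_f1(a[:k], b[:k]) == pytest.approx(expected, abs=1e-10)


class TestSilhouette:
    def test_two_tight_groups_score_high(self, rng):
        from spade_eeg.geometry import pairwise_matrix, random_spd
        A, B = random_spd(3, rng), random_spd(3, rng, scale=50.0)
        mats = np.stack([A + 0.001 * np.eye(3) * k for k in range(4)]
                        + [B + 0.001 * np.eye(3) * k for k in range(4)])
        D = pairwise_matrix(mats, "source")
        labels = [1, 1, 1, 1, 2, 2, 2, 2]
        assert riemannian_silhouette(labels, D) > 0.9

    def test_all_equal_distances_score_zero(self):
        D = np.ones((6, 6)) - np.eye(6)
        assert riemannian_silhouette([1, 1, 1, 2, 2, 2], D) == pytest.approx(0.0)

    def test_matches_independent_implementation(self, rng):
        pts = rng.standard_normal((12, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = rng.integers(1, 4, size=12)
        if len(np.unique(labels)) < 2:
            labels[0] = labels[0] % 3 + 1
        assert riemannian_silhouette(labels, D) == pytest.approx(
            _silhouette_oracle(labels, D), abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            riemannian_silhouette([1, 1, 1], np.zeros((3, 3)))


class TestCompareAlgorithms:
    def test_identical_scores_give_p_one(self, rng):
        v = rng.standard_normal(12)
        res = compare_algorithms({"ref": v, "other": v.copy()}, "ref")
        assert res.table["p"].iloc[0] == 1.0

    def test_uniform_improvement_is_highly_significant(self, rng):
        base = rng.uniform(0.2, 0.6, size=30)
        scores = {"ref": base + 0.2, "b1": base, "b2": base + rng.normal(0, 0.01, 30)}
        res = compare_algorithms(scores, "ref")
        assert res.table.set_index("algorithm").loc["b1", "p_adj"] < 1e-3

    def test_bh_adjustment_is_monotone_and_bounded_below_by_raw(self, rng):
        base = rng.uniform(0, 1, size=15)
        scores = {"ref": base + 0.3,
                  "a": base + rng.normal(0, 0.2, 15),
                  "b": base,
                  "c": base + rng.normal(0, 0.05, 15)}
        res = compare_algorithms(scores, "ref")
        assert (res.table["p_adj"] >= res.table["p"] - 1e-12).all()
        t = res.table.sort_values("p")
        assert t["p_adj"].is_monotonic_increasing

    def test_normality_gate_switches_test_family(self, rng):
        normal = {"ref": rng.normal(1.0, 0.1, 25), "b": rng.normal(0.5, 0.1, 25)}
        assert compare_algorithms(normal, "ref").test_used == "paired t"
        skewed = {"ref": rng.exponential(1.0, 25) ** 3, "b": rng.normal(0.5, 0.1, 25)}
        assert compare_algorithms(skewed, "ref").test_used == "wilcoxon"

    def test_unpaired_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_algorithms({"ref": np.ones(5), "b": np.ones(6)}, "ref")
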