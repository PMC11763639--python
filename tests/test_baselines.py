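"""Baseline clustering algorithms."""

import numpy as np
import pytest

from spade_eeg import baselines as bl
from spade_eeg._softdtw import sdtw_divergence
from spade_eeg.dec import EncoderSpec
from spade_eeg.geometry import random_spd
from spade_eeg.metrics import ari
from spade_eeg.segment import CovarianceSet, EEGRecord, SegmentSet, segment


def _two_pattern_record(rng, T=400, period=40):
    """Alternating single-channel-dominant topographies with clear GFP peaks."""
    data = 0.01 * rng.standard_normal((4, T))
    tt = np.arange(T)
    carrier = np.abs(np.sin(2 * np.pi * tt / period * 2))
    block = (tt // period) % 2
    data[0] += carrier * (block == 0) * 3.0
    data[1] += carrier * (block == 1) * 3.0
    truth = block + 1
    return EEGRecord(data, 1000.0), truth


def _template_covset(rng, s=2, copies=10, n=4, spread=0.01):
    templates = [random_spd(n, rng, scale=3.0 ** k) for k in range(s)]
    mats, truth = [], []
    for k, tpl in enumerate(templates):
        for _ in range(copies):
            noise = spread * rng.standard_normal((n, n))
            mats.append(tpl + noise @ noise.T)
            truth.append(k + 1)
    return CovarianceSet(np.stack(mats), 0.0), np.array(truth)


class TestGFP:
    def test_alternating_patterns_recovered(self, rng):
        rec, truth = _two_pattern_record(rng)
        labels = bl.gfp_microstates(rec, 2, seed=0)
        assert len(labels) == rec.n_samples
        assert ari(labels, truth) > 0.8

    def test_constant_signal_has_no_strict_maxima(self):
        rec = EEGRecord(np.ones((3, 50)) * np.array([[1.0], [2.0], [3.0]]), 1000.0)
        with pytest.raises(ValueError):
            bl.gfp_microstates(rec, 2, seed=0)

    def test_every_sample_labeled(self, rng):
        rec = EEGRecord(rng.standard_normal((5, 300)), 1000.0)
        labels = bl.gfp_microstates(rec, 4, seed=1)
        assert labels.shape == (300,)
        assert set(np.unique(labels)) <= {1, 2, 3, 4}


class TestGMM:
    def test_two_separated_gaussians_recovered_with_full_covariance(self, rng):
        X = np.concatenate([rng.standard_normal((300, 3)) * 0.2 + 5,
                            rng.standard_normal((300, 3)) * 0.2 - 5]).T
        truth = np.repeat([1, 2], 300)
        rec = EEGRecord(X, 1000.0)
        labels = bl.gmm_cluster(rec, 2, seed=0, covariance_type="full")
        assert ari(labels, truth) == 1.0

    def test_single_component_labels_everything_alike(self, rng):
        rec = EEGRecord(rng.standard_normal((3, 100)), 1000.0)
        assert len(np.unique(bl.gmm_cluster(rec, 1, seed=0))) == 1

    def test_mean_based_default_ignores_covariance_structure(self, rng):
        # two zero-mean regimes differing only in covariance: tied GMM ~ chance
        a = rng.standard_normal((500, 2)) @ np.array([[3.0, 0.0], [0.0, 0.1]])
        b = rng.standard_normal((500, 2)) @ np.array([[0.1, 0.0], [0.0, 3.0]])
        rec = EEGRecord(np.concatenate([a, b]).T, 1000.0)
        truth = np.repeat([1, 2], 500)
        assert ari(bl.gmm_cluster(rec, 2, seed=0), truth) < 0.2
        assert ari(bl.gmm_cluster(rec, 2, seed=0, covariance_type="full"),
                   truth) > 0.8


class TestSoftDTW:
    def test_divergence_of_series_with_itself_is_zero(self, rng):
        X = rng.standard_normal((30, 3))
        assert sdtw_divergence(X, X) == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_templates_cocluster(self, rng):
        t, n = 25, 3
        templates = [np.sin(2 * np.pi * (k + 1) * np.arange(t) / t)[None, :]
                     * np.ones((n, 1)) * (k + 1) for k in range(3)]
        segs, truth = [], []
        for k, tpl in enumerate(templates):
            for _ in range(6):
                segs.append(tpl + 0.01 * rng.standard_normal((n, t)))
                truth.append(k + 1)
        ss = SegmentSet(window_len=t, step=1, starts=np.arange(18),
                        segments=np.stack(segs), srate_hz=1000.0,
                        n_samples_total=t + 17)
        labels = bl.softdtw_cluster(ss, 3, seed=0)
        assert ari(labels, np.array(truth)) == 1.0

    def test_fixed_seed_reproducibility(self, rng):
        rec = EEGRecord(rng.standard_normal((3, 120)), 1000.0)
        ss = segment(rec, 20, 10)
        l1 = bl.softdtw_cluster(ss, 3, seed=5)
        l2 = bl.softdtw_cluster(ss, 3, seed=5)
        np.testing.assert_array_equal(l1, l2)


class TestSCMVectorKMeans:
    @pytest.mark.parametrize("n,expected", [(6, 21), (28, 406)])
    def test_vector_length(self, rng, n, expected):
        covs = CovarianceSet(np.stack([random_spd(n, rng) for _ in range(3)]), 0.0)
        assert bl.vectorize_scm(covs).shape == (3, expected)

    def test_templates_recovered(self, rng):
        covs, truth = _template_covset(rng)
        labels = bl.scm_vector_kmeans(covs, 2, seed=0)
        assert ari(labels, truth) == 1.0

    def test_identical_scms_give_single_effective_cluster(self, rng):
        C = random_spd(3, rng)
        covs = CovarianceSet(np.stack([C] * 8), 0.0)
        labels = bl.scm_vector_kmeans(covs, 1, seed=0)
        assert len(np.unique(labels)) == 1


class TestAEKMeans:
    def test_templates_recovered_and_reproducible(self, rng):
        covs, truth = _template_covset(rng, copies=15)
        spec = EncoderSpec(hidden_widths=(16, 8), latent_dim=2,
                           pretrain_epochs=150, seed=0)
        l1 = bl.ae_kmeans(covs, spec, 2, seed=0)
        l2 = bl.ae_kmeans(covs, spec, 2, seed=0)
        assert ari(l1, truth) == 1.0
        np.testing.assert_array_equal(l1, l2)


class TestTangentKMeans:
    def test_identical_scms_have_zero_tangent_vectors(self, rng):
        from spade_eeg.geometry import tangent_vectors
        C = random_spd(4, rng)
        vecs = tangent_vectors(np.stack([C] * 5))
        np.testing.assert_allclose(vecs, 0.0, atol=1e-8)

    def test_templates_recovered(self, rng):
        covs, truth = _template_covset(rng)
        labels = bl.tangent_kmeans(covs, 2, seed=0)
        assert ari(labels, truth) == 1.0

    def test_fixed_seed_reproducibility(self, rng):
        covs, _ = _template_covset(rng, s=3, copies=5)
        l1 = bl.tangent_kmeans(covs, 3, seed=2)
        l2 = bl.tangent_kmeans(covs, 3, seed=2)
        np.testing.assert_array_equal(l1, l2)
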