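"""SPD-manifold geometry: distances, means, maps, pairwise matrices."""

import numpy as np
import pytest

from spade_eeg.geometry import (
    FrechetMeanError,
    exp_map,
    frechet_mean,
    log_map,
    pairwise_both,
    pairwise_matrix,
    random_spd,
    riemannian_distance,
    sensor_distance,
    tangent_vectors,
)


class TestSensorDistance:
    def test_identical_matrices_give_one(self, rng):
        C = random_spd(4, rng)
        assert sensor_distance(C, C) == pytest.approx(1.0)

    def test_diagonal_closed_form_and_asymmetry(self):
        A = np.diag([4.0, 1.0])
        I = np.eye(2)
        assert sensor_distance(A, I, symmetrize=False) == pytest.approx(4.0)
        assert sensor_distance(I, A, symmetrize=False) == pytest.approx(1.0)
        assert sensor_distance(A, I) == pytest.approx(4.0)
        assert sensor_distance(I, A) == pytest.approx(4.0)

    def test_symmetrized_value_at_least_one(self, spd_set):
        for i in range(len(spd_set)):
            for j in range(len(spd_set)):
                assert sensor_distance(spd_set[i], spd_set[j]) >= 1.0 - 1e-12


class TestRiemannianDistance:
    def test_identity_of_indiscernibles(self, rng):
        C = random_spd(6, rng)
        assert riemannian_distance(C, C) == pytest.approx(0.0, abs=1e-9)

    def test_commuting_closed_form(self):
        assert riemannian_distance(np.diag([4.0, 1.0]), np.eye(2)) == \
            pytest.approx(np.log(4.0))

    def test_affine_invariance(self, rng):
        for _ in range(20):
            A, B = random_spd(4, rng), random_spd(4, rng)
            M = rng.standard_normal((4, 4))
            assert abs(riemannian_distance(M @ A @ M.T, M @ B @ M.T)
                       - riemannian_distance(A, B)) < 1e-8

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(30):
            A, B, C = (random_spd(3, rng) for _ in range(3))
            dab = riemannian_distance(A, B)
            dba = riemannian_distance(B, A)
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-8)
            assert dab <= riemannian_distance(A, C) + riemannian_distance(C, B) + 1e-8


class TestFrechetMean:
    def test_singleton_returns_input(self, rng):
        C = random_spd(4, rng)
        np.testing.assert_allclose(frechet_mean([C]), C)

    def test_repeated_matrix_converges_immediately(self, rng):
        C = random_spd(4, rng)
        np.testing.assert_allclose(frechet_mean(np.stack([C] * 5)), C, atol=1e-8)

    def test_commuting_matrices_give_geometric_mean(self):
        got = frechet_mean(np.stack([np.eye(2), np.diag([4.0, 4.0])]))
        np.testing.assert_allclose(got, np.diag([2.0, 2.0]), atol=1e-6)

    def test_congruence_equivariance(self, spd_set, rng):
        M = rng.standard_normal((5, 5))
        lhs = frechet_mean(np.stack([M @ C @ M.T for C in spd_set]))
        rhs = M @ frechet_mean(spd_set) @ M.T
        assert np.abs(lhs - rhs).max() < 1e-4 * np.abs(rhs).max()

    def test_nonconvergence_carries_last_iterate(self, spd_set):
        with pytest.raises(FrechetMeanError) as exc:
            frechet_mean(spd_set, tol=0.0, max_iter=2)
        assert exc.value.last_iterate.shape == (5, 5)


class TestLogExpMap:
    def test_base_point_maps_to_zero(self, rng):
        E = random_spd(4, rng)
        np.testing.assert_allclose(log_map(E, E), np.zeros((4, 4)), atol=1e-9)

    def test_identity_base_point_is_matrix_log(self, rng):
        C = random_spd(4, rng)
        w, V = np.linalg.eigh(C)
        np.testing.assert_allclose(log_map(np.eye(4), C),
                                   (V * np.log(w)) @ V.T, atol=1e-9)

    def test_whitened_norm_equals_distance(self, rng):
        E, C = random_spd(5, rng), random_spd(5, rng)
        w, V = np.linalg.eigh(E)
        isq = (V / np.sqrt(w)) @ V.T
        norm = np.linalg.norm(isq @ log_map(E, C) @ isq, "fro")
        assert norm == pytest.approx(riemannian_distance(E, C), abs=1e-8)

    def test_exp_inverts_log(self, rng):
        E, C = random_spd(4, rng), random_spd(4, rng)
        np.testing.assert_allclose(exp_map(E, log_map(E, C)), C, atol=1e-8)


class TestPairwise:
    def test_identical_pair_diagonals(self, rng):
        C = random_spd(3, rng)
        two = np.stack([C, C])
        np.testing.assert_allclose(pairwise_matrix(two, "source").values,
                                   np.zeros((2, 2)), atol=1e-8)
        np.testing.assert_allclose(pairwise_matrix(two, "sensor").values,
                                   np.ones((2, 2)), atol=1e-8)

    def test_matches_per_pair_recomputation(self, spd_set):
        sub = spd_set[:5]
        Dsen, Dsrc = pairwise_both(sub)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                assert Dsrc.values[i, j] == pytest.approx(
                    riemannian_distance(sub[i], sub[j]), abs=1e-9)
                assert Dsen.values[i, j] == pytest.approx(
                    sensor_distance(sub[i], sub[j]), abs=1e-9)

    def test_mixing_invariance_of_source_matrix(self, spd_set, rng):
        # distances between mixed-source SCMs equal source-space distances
        M = rng.standard_normal((5, 5))
        mixed = np.stack([M @ C @ M.T for C in spd_set])
        np.testing.assert_allclose(pairwise_matrix(mixed, "source").values,
                                   pairwise_matrix(spd_set, "source").values,
                                   atol=1e-7)


class TestTangentVectors:
    def test_weighted_vectorization_preserves_frobenius_norm(self, spd_set):
        base = frechet_mean(spd_set)
        vecs = tangent_vectors(spd_set, base=base, weighted=True)
        for k in range(len(spd_set)):
            L = log_map(base, spd_set[k])
            assert np.linalg.norm(vecs[k]) == pytest.approx(
                np.linalg.norm(L, "fro"), abs=1e-9)

    def test_vector_at_own_base_is_zero(self, rng):
        C = random_spd(4, rng)
        vecs = tangent_vectors(np.stack([C]), base=C)
        np.testing.assert_allclose(vecs, 0.0, atol=1e-9)
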