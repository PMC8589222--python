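import numpy as np
import pytest

from kfcmiss import _fitting as F
from kfcmiss.core import (
    FitConfig,
    fit_kfcm,
    fit_vkfcm,
    init_memberships,
    init_prototypes,
    multistart_fit,
    objective,
    update_memberships,
    update_prototypes,
    update_weights,
)
from kfcmiss.kernels import KernelSpec


def cfg2(**kw):
    base = dict(n_clusters=2, n_starts=1, seed=0)
    base.update(kw)
    return FitConfig(**base)


class TestInit:
    def test_membership_columns_sum_to_one_and_determinism(self):
        U = init_memberships(10, 3, seed=5)
        np.testing.assert_allclose(U.sum(axis=0), 1.0, atol=1e-12)
        assert U.shape == (3, 10)
        np.testing.assert_array_equal(U, init_memberships(10, 3, seed=5))

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            init_memberships(10, 1, seed=0)

    def test_prototypes_are_fuzzy_means(self):
        X = np.array([[0.0], [2.0]])
        U = np.array([[0.5, 0.5], [0.5, 0.5]])
        V = init_prototypes(X, U, m=2.0)
        np.testing.assert_allclose(V, [[1.0], [1.0]])

    def test_crisp_memberships_give_cluster_means(self):
        X = np.array([[1.0, 10.0], [3.0, 20.0], [100.0, 0.0]])
        U = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        V = init_prototypes(X, U, m=2.0)
        np.testing.assert_allclose(V[0], [2.0, 15.0])
        np.testing.assert_allclose(V[1], [100.0, 0.0])

    def test_equal_memberships_give_grand_mean(self, rng):
        X = rng.normal(size=(7, 3))
        U = np.full((2, 7), 0.5)
        V = init_prototypes(X, U, m=2.0)
        np.testing.assert_allclose(V, np.tile(X.mean(axis=0), (2, 1)))


class TestPrototypeUpdate:
    def test_fixed_point_at_coincident_data(self):
        X = np.full((4, 1), 3.0)
        U = np.full((2, 4), 0.5)
        spec = KernelSpec(np.array([1.0]))
        V = update_prototypes(X, U, np.full((2, 1), 3.0), spec, cfg2())
        np.testing.assert_allclose(V, 3.0)

    def test_single_point_pulls_prototype_to_itself(self):
        X = np.array([[5.0], [0.0], [1.0]])
        U = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        spec = KernelSpec(np.array([1.0]))
        V = update_prototypes(X, U, np.array([[2.0], [0.5]]), spec, cfg2(n_clusters=2))
        assert V[0, 0] == pytest.approx(5.0)

    def test_kernel_weighted_mean_hand_computed(self):
        # points {0, 2}, equal memberships, m = 2, v_old = 0, 2 sigma^2 = 4:
        # kernel weights are {1, e^-1}; new prototype = 2 e^-1 / (1 + e^-1)
        X = np.array([[0.0], [2.0]])
        U = np.full((2, 2), 0.5)
        spec = KernelSpec(np.array([4.0]))
        V = update_prototypes(X, U, np.array([[0.0], [0.0]]), spec, cfg2())
        expected = 2 * np.exp(-1) / (1 + np.exp(-1))
        assert V[0, 0] == pytest.approx(expected)
        assert expected == pytest.approx(0.537883, abs=1e-6)


class TestWeightUpdate:
    spec = KernelSpec(np.array([1.0, 1.0]))

    def test_symmetric_dispersions_give_unit_weights(self, rng):
        # two variables with identical per-cluster dispersion sums
        X = np.array([[0.0, 0.0], [1.0, 1.0], [-1.0, -1.0]])
        U = np.full((2, 3), 0.5)
        V = np.zeros((2, 2))
        Lam = update_weights(X, U, V, self.spec, cfg2())
        np.testing.assert_allclose(Lam, 1.0, atol=1e-12)

    def test_geometric_mean_closed_form(self):
        # S_k = (a, 4a) must give lambda = (2, 1/2) with product one
        W = np.array([[1.0, 1.0]])
        D = np.array([[[0.3, 1.2], [0.5, 2.0]]])  # S = (0.8, 3.2)
        Lam = F.weight_step(W, D)
        np.testing.assert_allclose(Lam, [[2.0, 0.5]])
        assert np.prod(Lam, axis=1) == pytest.approx(1.0)

    def test_zero_dispersion_is_floored_product_still_one(self):
        W = np.array([[1.0]])
        D = np.array([[[0.0, 2.0]]])
        Lam = F.weight_step(W, D, distance_floor=1e-12)
        assert np.isfinite(Lam).all()
        assert np.prod(Lam, axis=1)[0] == pytest.approx(1.0)


class TestMembershipUpdate:
    def test_equidistant_point_gets_uniform_membership(self):
        phi2 = np.full((4, 1), 0.7)
        U = F.membership_step(phi2, m=2.0)
        np.testing.assert_allclose(U, 0.25)

    def test_inverse_distance_closed_form(self):
        # m = 2, distances (1, 3) -> memberships (3/4, 1/4)
        U = F.membership_step(np.array([[1.0], [3.0]]), m=2.0)
        np.testing.assert_allclose(U[:, 0], [0.75, 0.25])

    def test_zero_distance_takes_full_membership(self):
        U = F.membership_step(np.array([[0.0], [2.0], [1.0]]), m=2.0)
        np.testing.assert_allclose(U[:, 0], [1.0, 0.0, 0.0])

    def test_two_zero_distances_split_equally(self):
        U = F.membership_step(np.array([[0.0], [0.0], [1.0]]), m=2.0)
        np.testing.assert_allclose(U[:, 0], [0.5, 0.5, 0.0])


class TestObjective:
    def test_crisp_perfect_fit_has_zero_objective(self):
        X = np.array([[1.0, 2.0], [5.0, 6.0]])
        U = np.eye(2)
        V = X.copy()
        Lam = np.ones((2, 2))
        spec = KernelSpec(np.array([1.0, 1.0]))
        assert objective(X, U, V, Lam, spec, cfg2()) == 0.0

    def test_single_point_single_weight(self):
        X = np.array([[1.0], [9.0]])
        V = np.array([[0.0], [9.0]])
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        spec = KernelSpec(np.array([2.0]))
        expected = 2 * (1 - np.exp(-0.5))
        assert objective(X, U, V, np.ones((2, 1)), spec, cfg2()) == pytest.approx(
            expected
        )

    def test_matches_term_by_term_loop(self, rng):
        X = rng.normal(size=(6, 3))
        U = init_memberships(6, 2, seed=3)
        V = rng.normal(size=(2, 3))
        Lam = np.exp(rng.normal(size=(2, 3)))
        Lam /= np.prod(Lam, axis=1, keepdims=True) ** (1 / 3)
        spec = KernelSpec(np.array([1.0, 2.0, 0.5]))
        m = 2.0
        brute = 0.0
        for k in range(2):
            for i in range(6):
                for j in range(3):
                    kj = np.exp(-((X[i, j] - V[k, j]) ** 2) / spec.two_sigma_sq[j])
                    brute += U[k, i] ** m * Lam[k, j] * 2 * (1 - kj)
        assert objective(X, U, V, Lam, spec, cfg2()) == pytest.approx(brute)


class TestFitVKFCM:
    def test_separated_blobs_recovered_exactly(self, small_blobs):
        X, y = small_blobs
        state = fit_vkfcm(X, cfg2(seed=4))
        pred = np.argmax(state.U, axis=0)
        # label-permutation invariant exact recovery
        assert len(set(zip(pred, y))) == 2
        assert state.converged

    def test_identical_rows_share_membership_equally(self):
        X = np.tile([1.0, 2.0], (6, 1))
        state = fit_vkfcm(X, cfg2(seed=1), spec=KernelSpec(np.array([1.0, 1.0])))
        np.testing.assert_allclose(state.U, 0.5, atol=1e-9)
        assert state.J_history[-1] == pytest.approx(0.0, abs=1e-12)

    def test_final_state_is_a_membership_fixed_point(self, small_blobs):
        X, _ = small_blobs
        state = fit_vkfcm(X, cfg2(seed=2))
        spec = KernelSpec(
            __import__("kfcmiss").estimate_bandwidths(X).two_sigma_sq
        )
        U_again = update_memberships(X, state.V, state.Lambda, spec, cfg2())
        np.testing.assert_allclose(U_again, state.U, atol=1e-8)

    def test_permuting_initial_memberships_permutes_solution(self, small_blobs):
        X, _ = small_blobs
        spec = KernelSpec(__import__("kfcmiss").estimate_bandwidths(X).two_sigma_sq)
        cfg = cfg2()
        U0 = init_memberships(X.shape[0], 2, seed=9)
        perm = np.array([1, 0])

        def run(U_init):
            U = U_init
            V = init_prototypes(X, U, cfg.m)
            for _ in range(5):
                V = update_prototypes(X, U, V, spec, cfg)
                Lam = update_weights(X, U, V, spec, cfg)
                U = update_memberships(X, V, Lam, spec, cfg)
            return U, V, Lam

        U_a, V_a, L_a = run(U0)
        U_b, V_b, L_b = run(U0[perm])
        np.testing.assert_allclose(U_b, U_a[perm], atol=1e-12)
        np.testing.assert_allclose(V_b, V_a[perm], atol=1e-12)
        np.testing.assert_allclose(L_b, L_a[perm], atol=1e-12)

    def test_unit_weights_reduce_to_unweighted_objective(self, small_blobs):
        X, _ = small_blobs
        spec = KernelSpec(__import__("kfcmiss").estimate_bandwidths(X).two_sigma_sq)
        U = init_memberships(X.shape[0], 2, seed=0)
        V = init_prototypes(X, U, 2.0)
        D = F.kernel_distances(X, V, spec.two_sigma_sq)
        unweighted = float(np.sum((U**2) * D.sum(axis=2)))
        assert objective(X, U, V, np.ones((2, 2)), spec, cfg2()) == pytest.approx(
            unweighted
        )


class TestMultistart:
    def test_single_start_equals_single_fit(self, small_blobs):
        X, _ = small_blobs
        cfg = cfg2(seed=6, n_starts=1)
        best, summary = multistart_fit(X, cfg)
        lone = fit_vkfcm(X, cfg)
        np.testing.assert_array_equal(best.U, lone.U)
        assert len(summary) == 1

    def test_best_objective_bounds_every_start(self, small_blobs):
        X, _ = small_blobs
        best, summary = multistart_fit(X, cfg2(seed=6, n_starts=8))
        assert (best.objective <= summary["objective"] + 1e-15).all()

    def test_same_master_seed_reproduces_best_state(self, small_blobs):
        X, _ = small_blobs
        b1, _ = multistart_fit(X, cfg2(seed=13, n_starts=4))
        b2, _ = multistart_fit(X, cfg2(seed=13, n_starts=4))
        np.testing.assert_array_equal(b1.U, b2.U)
        np.testing.assert_array_equal(b1.V, b2.V)


class TestKFCMBaseline:
    def test_separated_blobs_recovered(self, small_blobs):
        X, y = small_blobs
        state = fit_kfcm(X, cfg2(seed=1, n_starts=3))
        pred = np.argmax(state.U, axis=0)
        assert len(set(zip(pred, y))) == 2

    def test_equidistant_memberships_are_uniform(self):
        # membership update at equal kernel distances gives 1/K
        U = F.membership_step(np.array([[0.2], [0.2]]) * 2, m=2.0)
        np.testing.assert_allclose(U[:, 0], [0.5, 0.5])
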