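"""Divergence, prescreening, weighting and the local transfer solvers."""

import numpy as np
import pytest

from ltranshgg.core import PseudoCovariance, pseudo_covariance
from ltranshgg.mixture import EMConfig, penalized_em_fit
from ltranshgg.simulate import (NetworkSpec, generate_example1,
                                tridiagonal_precision)
from ltranshgg.transfer import (DivergenceRecord, InformativeSet,
                                adaptive_weights, aggregate_covariance,
                                bic_lambda2, delta_objective, divergence,
                                l1_inf_norm, lambda1_rule, local_transfer,
                                prescreen, solve_theta, theta_objective,
                                threshold_delta)
from conftest import random_pd_precision


def _pc(sigma, n=100.0, k=0, lp=0):
    return PseudoCovariance(sigma_tilde=np.asarray(sigma, float),
                            n_pseudo=n, domain_id=k, subgroup_id=lp)


def _record(asym, source=(0, 0), delta=None, p=2):
    if delta is None:
        delta = np.zeros((p, p))
    return DivergenceRecord(target_subgroup=0, source=source,
                            delta_matrix=delta, asym_norm=asym,
                            mean_diff_l1=0.0)


class TestDivergence:
    def test_exact_inverse_gives_zero(self, rng):
        sigma = np.linalg.inv(random_pd_precision(rng, 4))
        sigma = 0.5 * (sigma + sigma.T)
        rec = divergence(np.linalg.inv(sigma), _pc(sigma), np.zeros(4),
                         np.zeros(4))
        assert rec.asym_norm == pytest.approx(0.0, abs=1e-10)

    def test_identity_pair(self):
        rec = divergence(np.eye(3), _pc(np.eye(3)), np.zeros(3), np.ones(3))
        np.testing.assert_allclose(rec.delta_matrix, 0.0)
        assert rec.mean_diff_l1 == pytest.approx(3.0)

    def test_hand_computed_asym_norm(self):
        # choose theta0, sigma so that Delta = [[0, 1], [2, 0]]
        sigma = np.array([[2.0, 1.0], [1.0, 2.0]])
        M = np.array([[1.0, 1.0], [2.0, 1.0]])  # Delta + I
        theta0 = M @ np.linalg.inv(sigma)
        rec = divergence(theta0, _pc(sigma), np.zeros(2), np.zeros(2))
        np.testing.assert_allclose(rec.delta_matrix, [[0, 1], [2, 0]],
                                   atol=1e-12)
        assert rec.asym_norm == pytest.approx(4.0)


class TestPrescreen:
    def test_zero_divergence_always_included(self):
        iset = prescreen([_record(0.0)], np.eye(5), n_0l=10.0, p=5)
        assert iset.members == [(0, 0)]

    def test_threshold_arithmetic(self):
        """c=5, s_hat=3, p=100, n=200 -> threshold ~ 2.2761."""
        theta0 = tridiagonal_precision(100, 0.3)  # 3 nonzeros per column
        iset = prescreen([_record(2.5, source=(0, 0), p=100),
                          _record(2.0, source=(1, 0), p=100)],
                         theta0, n_0l=200.0, p=100, c=5.0)
        assert iset.s_hat == 3
        assert iset.threshold == pytest.approx(
            5 * 3 * np.sqrt(np.log(100) / 200), abs=1e-10)
        assert iset.threshold == pytest.approx(2.2761, abs=5e-4)
        assert iset.members == [(1, 0)]

    def test_all_divergent_gives_empty_set(self):
        iset = prescreen([_record(99.0), _record(50.0, source=(1, 1))],
                         np.eye(4), n_0l=100.0, p=4)
        assert iset.members == []

    def test_denoise_level_filters_small_entries(self):
        # dense small-entry divergence: huge raw norm, zero after filtering
        p = 40
        delta = np.full((p, p), 0.05)
        raw = l1_inf_norm(delta) + l1_inf_norm(delta.T)  # = 4.0
        rec = _record(raw, delta=delta, p=p)
        no_filter = prescreen([rec], np.eye(p), n_0l=400.0, p=p)
        assert no_filter.members == []
        filtered = prescreen([rec], np.eye(p), n_0l=400.0, p=p,
                             denoise_level=0.1)
        assert filtered.members == [(0, 0)]


class TestAdaptiveWeights:
    def _iset(self, members):
        return InformativeSet(target_subgroup=0, members=members,
                              threshold=1.0, c=5.0, s_hat=1, n_0l=10.0)

    def test_single_member_gets_unit_weight(self):
        delta = np.array([[0.5]])
        rec = _record(0.5, delta=delta, p=1)
        w = adaptive_weights(self._iset([(0, 0)]), [rec], {(0, 0): 10.0})
        assert w.alphas == {(0, 0): 1.0}

    def test_ratio_from_divergence_norms(self):
        r1 = _record(0, source=(0, 0), delta=np.array([[0.1]]))
        r2 = _record(0, source=(1, 0), delta=np.array([[0.2]]))
        w = adaptive_weights(self._iset([(0, 0), (1, 0)]), [r1, r2],
                             {(0, 0): 10.0, (1, 0): 10.0})
        assert w.alphas[(0, 0)] == pytest.approx(2 / 3)
        assert w.alphas[(1, 0)] == pytest.approx(1 / 3)

    def test_ratio_from_sample_sizes(self):
        r1 = _record(0, source=(0, 0), delta=np.array([[0.1]]))
        r2 = _record(0, source=(1, 0), delta=np.array([[0.1]]))
        w = adaptive_weights(self._iset([(0, 0), (1, 0)]), [r1, r2],
                             {(0, 0): 10.0, (1, 0): 30.0})
        assert w.alphas[(0, 0)] == pytest.approx(1 / 4)
        assert w.alphas[(1, 0)] == pytest.approx(3 / 4)

    def test_removing_member_preserves_remaining_ratios(self):
        recs = [_record(0, source=(k, 0),
                        delta=np.array([[0.1 * (k + 1)]])) for k in range(3)]
        sizes = {(k, 0): 10.0 for k in range(3)}
        w3 = adaptive_weights(self._iset([(k, 0) for k in range(3)]), recs,
                              sizes)
        w2 = adaptive_weights(self._iset([(0, 0), (1, 0)]), recs[:2], sizes)
        ratio3 = w3.alphas[(0, 0)] / w3.alphas[(1, 0)]
        ratio2 = w2.alphas[(0, 0)] / w2.alphas[(1, 0)]
        assert ratio3 == pytest.approx(ratio2)
        assert sum(w3.alphas.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            adaptive_weights(self._iset([]), [], {})


class TestAggregate:
    def test_single_member_unchanged(self, rng):
        sigma = np.linalg.inv(random_pd_precision(rng, 3))
        sigma = 0.5 * (sigma + sigma.T)
        from ltranshgg.transfer import TransferWeights
        w = TransferWeights(alphas={(0, 0): 1.0})
        np.testing.assert_allclose(
            aggregate_covariance(w, {(0, 0): _pc(sigma)}), sigma)

    def test_identical_members_any_weights(self):
        from ltranshgg.transfer import TransferWeights
        w = TransferWeights(alphas={(0, 0): 0.3, (1, 0): 0.7})
        out = aggregate_covariance(w, {(0, 0): _pc(np.eye(2)),
                                       (1, 0): _pc(np.eye(2))})
        np.testing.assert_allclose(out, np.eye(2))

    def test_convex_combination_arithmetic(self):
        from ltranshgg.transfer import TransferWeights
        w = TransferWeights(alphas={(0, 0): 0.25, (1, 0): 0.75})
        out = aggregate_covariance(w, {(0, 0): _pc(np.zeros((2, 2))),
                                       (1, 0): _pc(np.eye(2))})
        np.testing.assert_allclose(out, 0.75 * np.eye(2))

    def test_missing_pc_raises(self):
        from ltranshgg.transfer import TransferWeights
        w = TransferWeights(alphas={(0, 0): 1.0})
        with pytest.raises(KeyError):
            aggregate_covariance(w, {(9, 9): _pc(np.eye(2))})


class TestLambda1Rule:
    def test_identity_arithmetic(self):
        assert lambda1_rule(np.eye(100), 100, 200) == pytest.approx(
            2 * np.sqrt(np.log(100) / 200), abs=1e-12)
        assert lambda1_rule(np.eye(100), 100, 200) == pytest.approx(
            0.303486, abs=5e-6)

    def test_homogeneous_in_norm(self):
        assert lambda1_rule(2 * np.eye(100), 100, 200) == pytest.approx(
            2 * lambda1_rule(np.eye(100), 100, 200))


class TestThresholdDelta:
    def test_soft_threshold_entry(self):
        theta0 = np.array([[1.5]])
        sigma = np.array([[1.0]])  # M = 0.5
        assert threshold_delta(theta0, sigma, 0.2)[0, 0] == \
            pytest.approx(0.3)

    def test_zero_lambda_returns_m_exactly(self, rng):
        theta0 = random_pd_precision(rng, 3)
        sigma = np.linalg.inv(random_pd_precision(rng, 3))
        sigma = 0.5 * (sigma + sigma.T)
        M = theta0 @ sigma - np.eye(3)
        np.testing.assert_allclose(threshold_delta(theta0, sigma, 0.0), M)

    def test_optimality_against_random_perturbations(self, rng):
        theta0 = random_pd_precision(rng, 3)
        sigma = np.linalg.inv(random_pd_precision(rng, 3))
        sigma = 0.5 * (sigma + sigma.T)
        M = theta0 @ sigma - np.eye(3)
        lam = 0.1
        delta = threshold_delta(theta0, sigma, lam)
        base = delta_objective(delta, M, lam)
        # optimality sandwich at the obvious candidates
        assert base <= delta_objective(M, M, lam) + 1e-12
        assert base <= delta_objective(np.zeros_like(M), M, lam) + 1e-12
        for _ in range(10_000):
            pert = delta + rng.standard_normal((3, 3)) * \
                rng.choice([1e-3, 1e-2, 1e-1])
            assert base <= delta_objective(pert, M, lam) + 1e-12


def prox_gradient_oracle(A, b, lam, j, iters=20_000):
    """Independent proximal-gradient solver for one penalized column."""
    p = A.shape[0]
    step = 1.0 / np.linalg.eigvalsh(A)[-1]
    th = np.zeros(p)
    for _ in range(iters):
        grad = A @ th - b
        z = th - step * grad
        new = np.sign(z) * np.maximum(np.abs(z) - step * lam, 0.0)
        new[j] = z[j]  # diagonal coordinate unpenalized
        if np.max(np.abs(new - th)) < 1e-12:
            th = new
            break
        th = new
    return th


def column_objective(th, A, b, lam, j):
    pen = lam * (np.abs(th).sum() - abs(th[j]))
    return 0.5 * th @ A @ th - b @ th + pen


class TestSolveTheta:
    def test_identity_system(self):
        np.testing.assert_allclose(
            solve_theta(np.eye(4), np.zeros((4, 4)), 0.0), np.eye(4),
            atol=1e-10)

    def test_identity_sigma_closed_form(self):
        # with sigma = I each column is an independent soft threshold
        delta = np.array([[0.0, 0.4], [0.4, 0.0]])
        lam = 0.1
        theta = solve_theta(np.eye(2), delta, lam)
        np.testing.assert_allclose(np.diag(theta), 1.0, atol=1e-10)
        assert theta[0, 1] == pytest.approx(0.3)

    @pytest.mark.parametrize("p", [3, 4, 5])
    def test_matches_prox_gradient_oracle(self, p, rng):
        A = np.linalg.inv(random_pd_precision(rng, p))
        A = 0.5 * (A + A.T)
        delta = rng.standard_normal((p, p)) * 0.2
        lam = 0.1
        cols = solve_theta(A, delta, lam, tol=1e-9, max_iter=10_000,
                           return_columns=True)
        B = delta.T + np.eye(p)
        for j in range(p):
            oracle = prox_gradient_oracle(A, B[:, j], lam, j)
            assert column_objective(cols[:, j], A, B[:, j], lam, j) <= \
                column_objective(oracle, A, B[:, j], lam, j) + 1e-5

    def test_zero_diagonal_rejected(self):
        A = np.zeros((2, 2))
        with pytest.raises(ValueError):
            solve_theta(A, np.zeros((2, 2)), 0.1)

    def test_symmetrization_keeps_smaller_magnitude(self, rng):
        A = np.linalg.inv(random_pd_precision(rng, 4))
        A = 0.5 * (A + A.T)
        delta = rng.standard_normal((4, 4)) * 0.3
        theta = solve_theta(A, delta, 0.05)
        np.testing.assert_allclose(theta, theta.T, atol=1e-12)


class TestBicLambda2:
    def test_single_candidate(self):
        lam, theta, trace = bic_lambda2(np.eye(3), np.zeros((3, 3)),
                                        [0.5], n=100)
        assert lam == 0.5
        assert len(trace) == 1

    def test_tie_breaks_to_sparser_candidate(self):
        # sigma = I, delta = 0: both lambda2 = 0 and 10 give theta = I
        lam, theta, trace = bic_lambda2(np.eye(3), np.zeros((3, 3)),
                                        [0.0, 10.0], n=100)
        assert lam == 10.0
        np.testing.assert_allclose(theta, np.eye(3), atol=1e-8)
        assert len(trace) == 2
        assert trace[0][1] == pytest.approx(trace[1][1], abs=1e-9)


@pytest.fixture(scope="module")
def example1_fits():
    spec = NetworkSpec(kind="tridiagonal", p=20, seed=0)
    target, aux, truth = generate_example1(1, spec, 60, seed=5)
    tfit = penalized_em_fit(target, EMConfig(fixed_L=3, seed=5))
    afts = {k: penalized_em_fit(d, EMConfig(fixed_L=3, seed=5))
            for k, d in aux.items()}
    return target, aux, truth, tfit, afts


class TestLocalTransfer:
    def test_no_auxiliary_domains_is_vacuous(self, example1_fits):
        _, _, _, tfit, _ = example1_fits
        results = local_transfer(tfit, {}, {})
        assert all(not r.transferred for r in results)
        for r, g in zip(results, tfit.subgroups):
            np.testing.assert_array_equal(r.theta_hat, g.theta)

    def test_safeguard_on_all_dissimilar_sources(self):
        spec = NetworkSpec(kind="tridiagonal", p=20, seed=0)
        target, aux, _ = generate_example1(0, spec, 60, seed=6)
        tfit = penalized_em_fit(target, EMConfig(fixed_L=3, seed=6))
        afts = {k: penalized_em_fit(d, EMConfig(fixed_L=3, seed=6))
                for k, d in aux.items()}
        results = local_transfer(tfit, afts, aux)
        assert all(not r.transferred for r in results)
        for r, g in zip(results, tfit.subgroups):
            np.testing.assert_array_equal(r.theta_hat, g.theta)

    def test_informative_domain_enables_transfer(self, example1_fits):
        _, aux, truth, tfit, afts = example1_fits
        results = local_transfer(tfit, afts, aux)
        assert any(r.transferred for r in results)
        for r in results:
            if r.transferred:
                # weight mass concentrates on informative domain 0
                w_inf = sum(v for (k, _), v in r.weights.alphas.items()
                            if k == 0)
                assert w_inf > 0.5
                np.testing.assert_allclose(r.theta_hat, r.theta_hat.T,
                                           atol=1e-8)
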