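"""Mixture primitives: densities, responsibilities, pseudo covariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ltranshgg.core import (EmptySubgroupError, NotPositiveDefiniteError,
                            SampleMatrix, SubgroupParams, log_density,
                            observed_loglik, pseudo_covariance,
                            responsibilities)
from conftest import random_pd_precision

LOG_2PI = np.log(2 * np.pi)


@pytest.mark.parametrize("x, mu, theta, expected", [
    ([0.0], [0.0], [[1.0]], -0.5 * LOG_2PI),
    ([0.0, 0.0], [0.0, 0.0], np.eye(2), -LOG_2PI),
    ([0.0], [0.0], [[4.0]], -0.5 * LOG_2PI + 0.5 * np.log(4.0)),
])
def test_log_density_closed_forms(x, mu, theta, expected):
    params = SubgroupParams(pi=1.0, mu=np.asarray(mu),
                            theta=np.asarray(theta, dtype=float))
    assert log_density(np.asarray(x), params) == pytest.approx(expected,
                                                               abs=1e-9)


def test_log_density_matches_explicit_inverse(rng):
    """Cholesky evaluation agrees with the naive inverse/determinant form."""
    for p in range(1, 6):
        theta = random_pd_precision(rng, p)
        mu = rng.standard_normal(p)
        x = rng.standard_normal(p)
        params = SubgroupParams(pi=1.0, mu=mu, theta=theta)
        sigma = np.linalg.inv(theta)
        diff = x - mu
        naive = (-0.5 * p * LOG_2PI
                 - 0.5 * np.log(np.linalg.det(sigma))
                 - 0.5 * diff @ np.linalg.solve(sigma, diff))
        assert log_density(x, params) == pytest.approx(naive, abs=1e-8)


def test_log_density_rejects_non_pd():
    with pytest.raises(NotPositiveDefiniteError):
        SubgroupParams(pi=1.0, mu=np.zeros(2),
                       theta=np.array([[1.0, 2.0], [2.0, 1.0]]))


def test_subgroup_params_validates_sigma_cache():
    with pytest.raises(ValueError, match="inverse"):
        SubgroupParams(pi=1.0, mu=np.zeros(2), theta=np.eye(2),
                       sigma=2 * np.eye(2))


class TestResponsibilities:
    def test_single_component_is_unity(self, rng):
        data = SampleMatrix(values=rng.standard_normal((7, 3)))
        g = SubgroupParams(pi=1.0, mu=np.zeros(3), theta=np.eye(3))
        np.testing.assert_allclose(responsibilities(data, [g]), 1.0)

    def test_identical_components_split_evenly(self, rng):
        data = SampleMatrix(values=rng.standard_normal((5, 2)))
        gs = [SubgroupParams(pi=0.5, mu=np.zeros(2), theta=np.eye(2))
              for _ in range(2)]
        np.testing.assert_allclose(responsibilities(data, gs), 0.5)

    def test_far_separated_closed_form(self):
        # posterior for x=0 under means 0 and 10: 1 / (1 + exp(-50))
        data = SampleMatrix(values=np.array([[0.0], [0.0]]))
        gs = [SubgroupParams(pi=0.5, mu=np.array([0.0]), theta=np.eye(1)),
              SubgroupParams(pi=0.5, mu=np.array([10.0]), theta=np.eye(1))]
        gamma = responsibilities(data, gs)
        assert gamma[0, 0] == pytest.approx(1.0 / (1.0 + np.exp(-50.0)),
                                            rel=1e-12)

    def test_zero_proportion_rejected(self, rng):
        data = SampleMatrix(values=rng.standard_normal((4, 1)))
        with pytest.raises(ValueError):
            gs = [SubgroupParams(pi=1.0, mu=np.zeros(1), theta=np.eye(1))]
            gs[0].pi = 0.0  # bypass constructor check deliberately
            responsibilities(data, gs + gs)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 40),
           L=st.integers(1, 4))
    def test_rows_sum_to_one(self, seed, n, L):
        gen = np.random.default_rng(seed)
        p = 3
        data = SampleMatrix(values=gen.standard_normal((n, p)) * 3)
        pis = gen.dirichlet(np.ones(L))
        gs = [SubgroupParams(pi=float(pis[l]),
                             mu=gen.standard_normal(p) * 5,
                             theta=random_pd_precision(gen, p))
              for l in range(L)]
        gamma = responsibilities(data, gs)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(gamma >= 0) and np.all(gamma <= 1)


class TestPseudoCovariance:
    def test_uniform_weights_equal_biased_covariance(self, rng):
        X = rng.standard_normal((50, 4))
        data = SampleMatrix(values=X)
        mu = X.mean(axis=0)
        pc = pseudo_covariance(data, np.ones(50), mu)
        np.testing.assert_allclose(pc.sigma_tilde, np.cov(X.T, bias=True),
                                   atol=1e-10)
        assert pc.n_pseudo == pytest.approx(50.0)

    def test_two_point_hand_computation(self):
        data = SampleMatrix(values=np.array([[0.0], [2.0]]))
        pc = pseudo_covariance(data, np.array([1.0, 1.0]), np.array([1.0]))
        assert pc.sigma_tilde[0, 0] == pytest.approx(1.0)
        assert pc.n_pseudo == pytest.approx(2.0)

    def test_single_point_degenerates_to_zero(self, rng):
        X = rng.standard_normal((6, 3))
        data = SampleMatrix(values=X)
        gamma = np.zeros(6)
        gamma[0] = 1.0
        pc = pseudo_covariance(data, gamma, X[0])
        np.testing.assert_allclose(pc.sigma_tilde, 0.0, atol=1e-12)
        assert pc.n_pseudo == pytest.approx(1.0)

    def test_empty_subgroup_raises(self, rng):
        data = SampleMatrix(values=rng.standard_normal((5, 2)))
        with pytest.raises(EmptySubgroupError):
            pseudo_covariance(data, np.zeros(5), np.zeros(2))


class TestObservedLoglik:
    def test_single_component_equals_log_density(self):
        data = SampleMatrix(values=np.array([[0.0], [0.0]]))
        g = SubgroupParams(pi=1.0, mu=np.array([0.0]), theta=np.eye(1))
        # two identical rows, each contributing the standard-normal mode
        assert observed_loglik(data, [g]) == pytest.approx(-LOG_2PI, abs=1e-9)

    def test_identical_components_collapse(self, rng):
        data = SampleMatrix(values=rng.standard_normal((10, 2)))
        one = [SubgroupParams(pi=1.0, mu=np.zeros(2), theta=np.eye(2))]
        two = [SubgroupParams(pi=0.5, mu=np.zeros(2), theta=np.eye(2))
               for _ in range(2)]
        assert observed_loglik(data, two) == pytest.approx(
            observed_loglik(data, one), abs=1e-9)

    def test_two_component_direct_sum(self):
        data = SampleMatrix(values=np.array([[0.0], [0.0]]))
        gs = [SubgroupParams(pi=0.5, mu=np.array([0.0]), theta=np.eye(1)),
              SubgroupParams(pi=0.5, mu=np.array([10.0]), theta=np.eye(1))]
        f0 = np.exp(-0.5 * LOG_2PI)
        f10 = np.exp(-0.5 * LOG_2PI - 50.0)
        expected = 2 * np.log(0.5 * f0 + 0.5 * f10)
        assert observed_loglik(data, gs) == pytest.approx(expected, abs=1e-9)


def test_sample_matrix_rejects_missing_values():
    with pytest.raises(ValueError, match="missing"):
        SampleMatrix(values=np.array([[1.0, np.nan], [0.0, 1.0]]))
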