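"""Gaussian graphical mixture model (GGMM) primitives.

A GGMM models a heterogeneous sample as a finite mixture of multivariate
Gaussians, each component ("subgroup") carrying its own mean vector ``mu``
and sparse precision matrix ``theta`` (inverse covariance).  Zeros of
``theta`` encode conditional independencies, so each subgroup corresponds
to a distinct conditional-dependence network over the ``p`` features.

This module holds the numerical primitives every later stage builds on:
component log-densities parameterized by the precision matrix, E-step
responsibilities, observed-data log-likelihood, and responsibility-weighted
("pseudo") sample covariances with their pseudo sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "NotPositiveDefiniteError",
    "EmptySubgroupError",
    "SampleMatrix",
    "SubgroupParams",
    "PseudoCovariance",
    "log_density",
    "responsibilities",
    "pseudo_covariance",
    "observed_loglik",
]

#: smallest admissible Cholesky pivot; anything below is treated as non-PD
_CHOL_PIVOT_TOL = 1e-10

_LOG_2PI = np.log(2.0 * np.pi)


class NotPositiveDefiniteError(ValueError):
    """Raised when a precision matrix is not positive definite."""


class EmptySubgroupError(ValueError):
    """Raised when a pseudo-subgroup carries (numerically) zero weight."""


@dataclass
class SampleMatrix:
    """An ``n x p`` sample-by-feature data matrix for one domain.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Real-valued observations, one sample per row.  No missing entries.
    domain_id : str
        ``"target"`` or a label identifying an auxiliary domain.
    feature_names : sequence of str, optional
        Length-``p`` feature labels (e.g. gene symbols).
    """

    values: np.ndarray
    domain_id: str = "target"
    feature_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n x p) array")
        if self.values.shape[0] < 2:
            raise ValueError("need at least two samples (n >= 2)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"domain {self.domain_id!r}: values contain missing or "
                "non-finite entries"
            )
        if self.feature_names is not None:
            self.feature_names = list(self.feature_names)
            if len(self.feature_names) != self.values.shape[1]:
                raise ValueError("feature_names length does not match p")
            if len(set(self.feature_names)) != len(self.feature_names):
                raise ValueError("duplicate feature names")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def _cholesky_precision(theta: np.ndarray, label: object = None) -> np.ndarray:
    """Lower Cholesky factor of a precision matrix, with an explicit PD check."""
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise ValueError("theta must be a square matrix")
    if not np.allclose(theta, theta.T, atol=1e-8):
        raise ValueError("theta must be symmetric (tolerance 1e-8)")
    try:
        chol = np.linalg.cholesky(theta)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            f"precision matrix{_fmt_label(label)} is not positive definite"
        ) from None
    if np.min(np.diag(chol)) <= _CHOL_PIVOT_TOL:
        raise NotPositiveDefiniteError(
            f"precision matrix{_fmt_label(label)} is numerically singular "
            f"(smallest Cholesky pivot <= {_CHOL_PIVOT_TOL})"
        )
    return chol


def _fmt_label(label: object) -> str:
    return "" if label is None else f" of subgroup {label!r}"


@dataclass
class SubgroupParams:
    """Parameters of one mixture component: (pi, mu, theta).

    ``theta`` is the precision matrix; ``sigma``, when present, caches its
    inverse and is validated against ``theta``.
    """

    pi: float
    mu: np.ndarray
    theta: np.ndarray
    sigma: Optional[np.ndarray] = None
    _chol: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.theta = np.asarray(self.theta, dtype=float)
        if not (0.0 < self.pi <= 1.0):
            raise ValueError(f"mixing proportion pi={self.pi} not in (0, 1]")
        if self.theta.shape != (self.p, self.p):
            raise ValueError("theta shape does not match mu length")
        self._chol = _cholesky_precision(self.theta)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if not np.allclose(self.theta @ self.sigma, np.eye(self.p), atol=1e-6):
                raise ValueError("sigma is not the inverse of theta (tol 1e-6)")

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        """Inverse of ``theta``, computed (and cached) on demand."""
        if self.sigma is None:
            identity = np.eye(self.p)
            half = np.linalg.solve(self._chol, identity)
            self.sigma = half.T @ half
        return self.sigma


@dataclass
class PseudoCovariance:
    """Responsibility-weighted covariance of one subgroup in one domain.

    ``sigma_tilde`` is the weighted outer-product average around the
    subgroup mean; ``n_pseudo`` the sum of responsibilities, i.e. the
    effective ("pseudo") number of samples attributable to the subgroup.
    """

    sigma_tilde: np.ndarray
    n_pseudo: float
    domain_id: str = ""
    subgroup_id: int = 0

    def __post_init__(self) -> None:
        self.sigma_tilde = np.asarray(self.sigma_tilde, dtype=float)
        if not np.allclose(self.sigma_tilde, self.sigma_tilde.T, atol=1e-8):
            raise ValueError("sigma_tilde must be symmetric")
        if self.n_pseudo < 0:
            raise ValueError("n_pseudo must be nonnegative")


def _log_density_many(x: np.ndarray, params: SubgroupParams,
                      label: object = None) -> np.ndarray:
    """Vectorized log N(x; mu, theta^{-1}) for rows of ``x``."""
    chol = params._chol
    if chol is None:  # pragma: no cover - defensive, set in __post_init__
        chol = _cholesky_precision(params.theta, label)
    p = params.p
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    centered = np.atleast_2d(x) - params.mu
    # quadratic form (x-mu)' Theta (x-mu) = ||L' (x-mu)||^2 with Theta = L L'
    half = centered @ chol
    quad = np.einsum("ij,ij->i", half, half)
    return 0.5 * logdet - 0.5 * p * _LOG_2PI - 0.5 * quad


def log_density(x: np.ndarray, params: SubgroupParams) -> float:
    """Log multivariate normal density with mean ``mu``, covariance ``theta``^-1.

    Evaluated through the Cholesky factor of the precision matrix, so no
    inverse or determinant of the covariance is ever formed.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != params.p:
        raise ValueError("x length does not match parameter dimension")
    return float(_log_density_many(x[None, :], params)[0])


def responsibilities(data: SampleMatrix,
                     subgroups: Sequence[SubgroupParams]) -> np.ndarray:
    """Posterior component probabilities (the E-step), computed in log space.

    Row ``i``, column ``l`` is ``pi_l f_l(x_i) / sum_m pi_m f_m(x_i)``.
    A log-sum-exp max shift guards against underflow, so every row sums
    to one even for extremely well-separated components.
    """
    L = len(subgroups)
    if L < 1:
        raise ValueError("need at least one subgroup")
    pis = np.array([g.pi for g in subgroups], dtype=float)
    if np.any(pis <= 0):
        raise ValueError("all mixing proportions must be positive")
    if not np.isclose(pis.sum(), 1.0, atol=1e-6):
        raise ValueError(f"mixing proportions sum to {pis.sum():.6f}, not 1")
    log_w = np.empty((data.n, L))
    for l, g in enumerate(subgroups):
        log_w[:, l] = np.log(g.pi) + _log_density_many(data.values, g, l)
    log_norm = logsumexp(log_w, axis=1, keepdims=True)
    return np.exp(log_w - log_norm)


def pseudo_covariance(data: SampleMatrix, gamma_col: np.ndarray,
                      mu: np.ndarray, domain_id: str = "",
                      subgroup_id: int = 0) -> PseudoCovariance:
    """Responsibility-weighted covariance and pseudo sample size.

    ``sigma_tilde = sum_i gamma_i (x_i - mu)(x_i - mu)' / sum_i gamma_i``
    and ``n_pseudo = sum_i gamma_i``.  The result is symmetric PSD by
    construction.
    """
    gamma_col = np.asarray(gamma_col, dtype=float).ravel()
    if gamma_col.shape[0] != data.n:
        raise ValueError("gamma_col length does not match number of samples")
    if np.any(gamma_col < -1e-12) or np.any(gamma_col > 1.0 + 1e-12):
        raise ValueError("responsibilities must lie in [0, 1]")
    weight = float(gamma_col.sum())
    if weight <= np.finfo(float).eps:
        raise EmptySubgroupError(
            f"empty pseudo-subgroup (domain={domain_id!r}, "
            f"subgroup={subgroup_id}): responsibility mass is zero"
        )
    centered = data.values - np.asarray(mu, dtype=float).ravel()
    weighted = centered * gamma_col[:, None]
    sigma = (weighted.T @ centered) / weight
    sigma = 0.5 * (sigma + sigma.T)
    return PseudoCovariance(sigma_tilde=sigma, n_pseudo=weight,
                            domain_id=domain_id, subgroup_id=subgroup_id)


def observed_loglik(data: SampleMatrix,
                    subgroups: Sequence[SubgroupParams]) -> float:
    """Observed-data log-likelihood ``sum_i log sum_l pi_l f_l(x_i)``."""
    L = len(subgroups)
    if L < 1:
        raise ValueError("need at least one subgroup")
    log_w = np.empty((data.n, L))
    for l, g in enumerate(subgroups):
        log_w[:, l] = np.log(g.pi) + _log_density_many(data.values, g, l)
    return float(np.sum(logsumexp(log_w, axis=1)))
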