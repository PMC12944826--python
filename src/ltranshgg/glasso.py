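"""Weighted graphical lasso via ADMM.

Solves, over positive-definite precision matrices ``Theta``,

    minimize  tr(S Theta) - log det Theta + sum_{i != j} P_ij |Theta_ij|

with an elementwise nonnegative penalty matrix ``P`` (zero on the
diagonal).  An entrywise penalty is needed because the mixture M-step
scales the l1 penalty per component, and allows adaptive weighting.

The alternating-direction method of multipliers splits the smooth
log-det term from the l1 term: the Theta-update is a closed-form
eigenvalue shrinkage, the Z-update an elementwise soft threshold.  The
returned iterate is Z, whose entries are exactly zero where the penalty
bites, which is what support-recovery consumers rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["weighted_graphical_lasso", "refit_support",
           "GlassoConvergenceError", "soft_threshold"]


class GlassoConvergenceError(RuntimeError):
    """ADMM failed to reach the residual tolerance.

    Carries the last iterate and the final primal/dual residuals so a
    caller can inspect how far the solver got.
    """

    def __init__(self, message: str, last_iterate: np.ndarray,
                 primal_residual: float, dual_residual: float):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.primal_residual = primal_residual
        self.dual_residual = dual_residual


def soft_threshold(x: np.ndarray, thresh: np.ndarray) -> np.ndarray:
    """Elementwise soft threshold ``sign(x) max(|x| - thresh, 0)``."""
    return np.sign(x) * np.maximum(np.abs(x) - thresh, 0.0)


def glasso_objective(theta: np.ndarray, S: np.ndarray,
                     penalty: np.ndarray) -> float:
    """Penalized negative log-likelihood objective (per-sample scale)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    return float(np.sum(S * theta) - logdet + np.sum(penalty * np.abs(theta)))


def weighted_graphical_lasso(S: np.ndarray, penalty: np.ndarray,
                             rho: float = 1.0, max_iter: int = 500,
                             tol: float = 1e-5,
                             init: np.ndarray | None = None) -> np.ndarray:
    """Sparse precision estimate for covariance ``S`` under penalty ``P``.

    Parameters
    ----------
    S : (p, p) ndarray
        Symmetric positive-semidefinite covariance-type matrix.
    penalty : (p, p) ndarray
        Symmetric, nonnegative, zero-diagonal penalty weights; entry
        ``P_ij`` multiplies ``|Theta_ij|`` in the objective.
    rho : float
        ADMM augmented-Lagrangian parameter.
    max_iter, tol : int, float
        Iteration cap and residual tolerance (Frobenius, relative to p).
    init : (p, p) ndarray, optional
        Warm start for the sparse iterate.

    Returns
    -------
    (p, p) ndarray
        Symmetric positive-definite precision matrix with exact zeros
        where the penalty prevails.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be square symmetric")
    penalty = np.asarray(penalty, dtype=float)
    if penalty.shape != (p, p):
        raise ValueError("penalty shape mismatch")
    if np.any(penalty < 0):
        raise ValueError("penalty must be nonnegative")
    if np.any(np.abs(np.diag(penalty)) > 0):
        raise ValueError("penalty diagonal must be zero")

    Z = np.asarray(init, dtype=float).copy() if init is not None else \
        np.diag(1.0 / np.maximum(np.diag(S), 1e-6))
    U = np.zeros((p, p))
    thresh = penalty / rho
    primal = dual = np.inf
    for _ in range(max_iter):
        # Theta-update: argmin tr(S T) - logdet T + rho/2 ||T - Z + U||_F^2
        vals, vecs = np.linalg.eigh(rho * (Z - U) - S)
        shrunk = (vals + np.sqrt(vals ** 2 + 4.0 * rho)) / (2.0 * rho)
        theta = (vecs * shrunk) @ vecs.T
        # Z-update: elementwise soft threshold (diagonal unpenalized)
        Z_old = Z
        Z = soft_threshold(theta + U, thresh)
        U = U + theta - Z
        primal = np.linalg.norm(theta - Z) / max(1.0, np.sqrt(p))
        dual = rho * np.linalg.norm(Z - Z_old) / max(1.0, np.sqrt(p))
        if primal < tol and dual < tol:
            break
    else:
        raise GlassoConvergenceError(
            f"weighted graphical lasso did not converge in {max_iter} "
            f"iterations (primal {primal:.2e}, dual {dual:.2e})",
            last_iterate=Z, primal_residual=primal, dual_residual=dual,
        )
    Z = 0.5 * (Z + Z.T)
    # Z carries the exact zeros; fall back to the PD iterate theta if the
    # thresholded copy lost definiteness (possible at loose tolerance).
    if np.min(np.linalg.eigvalsh(Z)) <= 1e-10:
        theta = 0.5 * (theta + theta.T)
        theta[np.abs(theta) < 1e-10] = 0.0
        return theta
    return Z


def refit_support(S: np.ndarray, support: np.ndarray,
                  rho: float = 1.0, max_iter: int = 1000,
                  tol: float = 1e-6) -> np.ndarray:
    """Support-constrained Gaussian MLE of the precision matrix.

    Maximizes the Gaussian log-likelihood subject to ``Theta_ij = 0``
    outside the given off-diagonal support — the usual debiasing refit
    after an l1 solution, removing the shrinkage bias on retained
    entries while keeping the selected sparsity pattern.  Implemented
    as the penalty-matrix ADMM with zero penalty on the support and an
    effectively infinite penalty off it.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    support = np.asarray(support, dtype=bool)
    big = 1e8 * (np.abs(S).max() + 1.0)
    penalty = np.where(support, 0.0, big)
    np.fill_diagonal(penalty, 0.0)
    return weighted_graphical_lasso(S, penalty, rho=rho, max_iter=max_iter,
                                    tol=tol)
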