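"""Subgroup-local transfer of precision matrices.

Given initial mixture fits for a target domain and ``K`` auxiliary
domains, each target subgroup ``l`` borrows strength only from auxiliary
subgroups whose distribution is provably close to it:

1.  **Divergence.** For every auxiliary subgroup ``(k, l')`` compute
    ``Delta = Theta_l^(0) SigmaTilde_{l'}^(k) - I``; its symmetrized
    max-column-l1 norm measures how far the pair is from sharing a
    precision matrix.
2.  **Prescreening.** Keep pairs whose divergence norm is below
    ``c * s_hat * sqrt(log p / n_0l)`` — the single-domain estimation
    error order — with hard-threshold constant ``c`` (default 5).  An
    empty set terminates transfer for that subgroup: the initial
    estimate is returned unchanged, which is the safeguard against
    negative transfer.
3.  **Adaptive weighting.** Retained pseudo covariances are averaged
    with weights proportional to ``n_{kl'} / ||Delta||_{1,inf}``, so
    larger and closer sources dominate.
4.  **Local transfer.**  The divergence of the aggregate is
    soft-thresholded at ``lambda_1``, and the subgroup precision is
    re-estimated column by column from the aggregated covariance via an
    l1-penalized quadratic program, with ``lambda_2`` tuned by a
    BIC-type criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import PseudoCovariance, SampleMatrix, pseudo_covariance
from .glasso import soft_threshold
from .mixture import GGMMResults

logger = logging.getLogger(__name__)

__all__ = [
    "DivergenceRecord",
    "InformativeSet",
    "TransferWeights",
    "TransferResult",
    "TransferConfig",
    "LocalTransfer",
    "LocalTransferResults",
    "divergence",
    "prescreen",
    "adaptive_weights",
    "aggregate_covariance",
    "lambda1_rule",
    "threshold_delta",
    "solve_theta",
    "bic_lambda2",
    "local_transfer",
]

_ZERO_TOL = 1e-8
#: denominator floor for a source with exactly zero divergence, so a
#: perfect match dominates finitely instead of dividing by zero
_WEIGHT_FLOOR = 1e-8


def l1_inf_norm(A: np.ndarray) -> float:
    """Maximum column l1 norm ``max_j sum_i |A_ij|``."""
    return float(np.max(np.abs(A).sum(axis=0)))


@dataclass
class DivergenceRecord:
    """Divergence of one auxiliary subgroup from one target subgroup."""

    target_subgroup: int
    source: Tuple[int, int]
    delta_matrix: np.ndarray
    asym_norm: float
    mean_diff_l1: float


@dataclass
class InformativeSet:
    """Prescreened informative auxiliary subgroups for one target subgroup."""

    target_subgroup: int
    members: List[Tuple[int, int]]
    threshold: float
    c: float
    s_hat: int
    n_0l: float


@dataclass
class TransferWeights:
    """Normalized aggregation weights keyed by (domain, subgroup)."""

    alphas: Dict[Tuple[int, int], float]

    def __post_init__(self) -> None:
        if self.alphas:
            total = sum(self.alphas.values())
            if not np.isclose(total, 1.0, atol=1e-10):
                raise ValueError(f"weights sum to {total}, not 1")
            if any(v < 0 for v in self.alphas.values()):
                raise ValueError("weights must be nonnegative")


@dataclass
class TransferResult:
    """Post-transfer estimate for one target subgroup.

    When ``transferred`` is False the safeguard fired and ``theta_hat``
    is exactly the initialization-stage estimate.
    """

    target_subgroup: int
    transferred: bool
    theta_hat: np.ndarray
    delta_hat: Optional[np.ndarray] = None
    sigma_A: Optional[np.ndarray] = None
    lambda1: Optional[float] = None
    lambda2: Optional[float] = None
    bic_trace: List[Tuple[float, float]] = field(default_factory=list)
    informative_set: Optional[InformativeSet] = None
    weights: Optional[TransferWeights] = None


@dataclass
class TransferConfig:
    """Constants of the prescreening / transfer stage."""

    c: float = 5.0
    lambda2_grid: Optional[Sequence[float]] = None
    cd_tol: float = 1e-6
    cd_max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")


def divergence(theta0: np.ndarray, pc: PseudoCovariance,
               mu0: np.ndarray, mu_aux: np.ndarray,
               target_subgroup: int = 0) -> DivergenceRecord:
    """Divergence record between a target subgroup and one auxiliary source.

    ``Delta = theta0 @ sigma_tilde - I``; the reported ``asym_norm`` is
    ``||Delta||_{1,inf} + ||Delta^T||_{1,inf}`` (it symmetrizes the
    max-column-l1 norm, which is not invariant under transposition).
    """
    theta0 = np.asarray(theta0, dtype=float)
    p = theta0.shape[0]
    if pc.sigma_tilde.shape != (p, p):
        raise ValueError("dimension mismatch between theta0 and sigma_tilde")
    mu0 = np.asarray(mu0, dtype=float).ravel()
    mu_aux = np.asarray(mu_aux, dtype=float).ravel()
    if mu0.shape != mu_aux.shape or mu0.shape[0] != p:
        raise ValueError("dimension mismatch between mean vectors")
    delta = theta0 @ pc.sigma_tilde - np.eye(p)
    return DivergenceRecord(
        target_subgroup=target_subgroup,
        source=(pc.domain_id, pc.subgroup_id),
        delta_matrix=delta,
        asym_norm=l1_inf_norm(delta) + l1_inf_norm(delta.T),
        mean_diff_l1=float(np.abs(mu0 - mu_aux).sum()),
    )


def _screening_norm(record: DivergenceRecord, denoise_level: float) -> float:
    """Asymmetric divergence norm, optionally on a noise-filtered matrix.

    At ``denoise_level > 0`` entries of ``Delta`` below that level are
    soft-thresholded to zero before taking the norm.  Sampling noise in
    a pseudo covariance alone inflates the max-column-l1 norm of the raw
    divergence roughly like ``p / sqrt(n_aux)``, which at realistic
    sizes exceeds any threshold of order ``sqrt(log p / n)``; filtering
    at the entrywise noise scale leaves structural divergence visible.
    """
    if denoise_level <= 0:
        return record.asym_norm
    d = soft_threshold(record.delta_matrix, denoise_level)
    return l1_inf_norm(d) + l1_inf_norm(d.T)


def prescreen(records: Sequence[DivergenceRecord], theta0: np.ndarray,
              n_0l: float, p: int, c: float = 5.0,
              target_subgroup: int = 0,
              denoise_level: float = 0.0) -> InformativeSet:
    """Hard-threshold screening of auxiliary subgroups.

    Threshold ``c * s_hat * sqrt(log p / n_0l)`` with ``s_hat`` the
    maximum number of nonzeros in any column of ``theta0`` — the
    estimation-error order achievable from the target subgroup alone.
    Sources at or below the threshold are retained in input order.
    An empty result is valid and triggers the no-transfer safeguard.
    ``denoise_level`` soft-thresholds the divergence entries before the
    norm is taken (see :func:`_screening_norm`); at 0 the raw recorded
    norm is compared.
    """
    if n_0l <= 0:
        raise ValueError("n_0l must be positive")
    if p < 2:
        raise ValueError("p must be >= 2")
    theta0 = np.asarray(theta0, dtype=float)
    s_hat = int(np.max(np.sum(np.abs(theta0) > _ZERO_TOL, axis=0)))
    threshold = c * s_hat * np.sqrt(np.log(p) / n_0l)
    members = [r.source for r in records
               if _screening_norm(r, denoise_level) <= threshold]
    return InformativeSet(target_subgroup=target_subgroup, members=members,
                          threshold=float(threshold), c=c, s_hat=s_hat,
                          n_0l=float(n_0l))


def adaptive_weights(iset: InformativeSet,
                     records: Sequence[DivergenceRecord],
                     pseudo_sizes: Dict[Tuple[int, int], float],
                     denoise_level: float = 0.0) -> TransferWeights:
    """Similarity- and size-driven aggregation weights.

    ``alpha_{kl'}`` is proportional to ``n_{kl'} / ||Delta||_{1,inf}``
    (one-sided norm), normalized to sum to one over the informative set.
    A zero divergence gets a floor of 1e-8 in the denominator so a
    perfect match dominates finitely.  ``denoise_level`` applies the
    same entrywise soft threshold as in prescreening before the norm.
    """
    if not iset.members:
        raise ValueError("informative set is empty: use the no-transfer "
                         "safeguard instead of weighting")
    by_source = {r.source: r for r in records}
    raw = {}
    for src in iset.members:
        rec = by_source[src]
        delta = (soft_threshold(rec.delta_matrix, denoise_level)
                 if denoise_level > 0 else rec.delta_matrix)
        denom = max(l1_inf_norm(delta), _WEIGHT_FLOOR)
        raw[src] = pseudo_sizes[src] / denom
    total = sum(raw.values())
    return TransferWeights(alphas={s: v / total for s, v in raw.items()})


def aggregate_covariance(weights: TransferWeights,
                         pcs: Dict[Tuple[int, int], PseudoCovariance]
                         ) -> np.ndarray:
    """Convex combination of informative pseudo covariances."""
    if not weights.alphas:
        raise ValueError("no weights to aggregate")
    missing = set(weights.alphas) - set(pcs)
    if missing:
        raise KeyError(f"pseudo covariances missing for sources {missing}")
    out = None
    for src, alpha in weights.alphas.items():
        term = alpha * pcs[src].sigma_tilde
        out = term if out is None else out + term
    return 0.5 * (out + out.T)


def lambda1_rule(theta0: np.ndarray, p: int, n: int) -> float:
    """Thresholding level ``2 ||theta0||_{1,inf} sqrt(log p / n)``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return 2.0 * l1_inf_norm(np.asarray(theta0, dtype=float)) * \
        np.sqrt(np.log(p) / n)


def threshold_delta(theta0: np.ndarray, sigma_A: np.ndarray,
                    lambda1: float) -> np.ndarray:
    """Adaptive thresholding of the aggregate divergence.

    The penalized least-squares problem
    ``argmin_Delta 1/2 tr(Delta' Delta) - tr(M' Delta) + lambda1 ||Delta||_1``
    with ``M = theta0 sigma_A - I`` separates elementwise, so the
    solution is the soft threshold of ``M`` at ``lambda1``.
    """
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    M = np.asarray(theta0, float) @ np.asarray(sigma_A, float) - \
        np.eye(theta0.shape[0])
    return soft_threshold(M, lambda1)


def delta_objective(delta: np.ndarray, M: np.ndarray,
                    lambda1: float) -> float:
    """Objective of the thresholding problem (for optimality checks)."""
    return float(0.5 * np.sum(delta * delta) - np.sum(M * delta) +
                 lambda1 * np.abs(delta).sum())


class SolverConvergenceError(RuntimeError):
    """Coordinate descent failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def solve_theta(sigma_A: np.ndarray, delta_hat: np.ndarray, lambda2: float,
                tol: float = 1e-6, max_iter: int = 2000,
                return_columns: bool = False) -> np.ndarray:
    """l1-penalized columnwise precision estimate from the aggregate.

    Column ``j`` solves
    ``min 1/2 th' sigma_A th - b' th + lambda2 sum_{i != j} |th_i|``
    with ``b`` the j-th column of ``delta_hat' + I`` (the diagonal
    coordinate is unpenalized), by cyclic coordinate descent with
    closed-form soft-threshold updates.  The stacked columns are then
    symmetrized by keeping, of each (i, j)/(j, i) pair, the entry of
    smaller magnitude.  ``return_columns=True`` skips the
    symmetrization and returns the raw column-stacked solution.
    """
    A = np.asarray(sigma_A, dtype=float)
    p = A.shape[0]
    if lambda2 < 0:
        raise ValueError("lambda2 must be nonnegative")
    diag = np.diag(A)
    if np.any(diag <= 0):
        raise ValueError("sigma_A has a nonpositive diagonal entry; "
                         "coordinate updates are undefined")
    B = np.asarray(delta_hat, dtype=float).T + np.eye(p)
    theta = np.zeros((p, p))
    for j in range(p):
        b = B[:, j]
        th = theta[:, j]
        th[j] = b[j] / diag[j]
        Ath = A @ th
        for _ in range(max_iter):
            max_change = 0.0
            for i in range(p):
                r = b[i] - Ath[i] + diag[i] * th[i]
                if i == j:
                    new = r / diag[i]
                else:
                    new = np.sign(r) * max(abs(r) - lambda2, 0.0) / diag[i]
                change = new - th[i]
                if change != 0.0:
                    Ath += A[:, i] * change
                    th[i] = new
                    max_change = max(max_change, abs(change))
            if max_change < tol:
                break
        else:
            raise SolverConvergenceError(
                f"column {j} of the precision solver did not converge "
                f"(last update {max_change:.2e})", residual=max_change)
        theta[:, j] = th
    if return_columns:
        return theta
    smaller = np.where(np.abs(theta) <= np.abs(theta.T), theta, theta.T)
    return smaller


def theta_objective(theta: np.ndarray, sigma_A: np.ndarray,
                    delta_hat: np.ndarray, lambda2: float) -> float:
    """Full objective of the transfer precision problem."""
    p = theta.shape[0]
    G = np.asarray(delta_hat).T + np.eye(p)
    off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
    return float(0.5 * np.sum(theta * (sigma_A @ theta)) -
                 np.sum(G * theta) + lambda2 * off)


def default_lambda2_grid(p: int, n: int, size: int = 20) -> np.ndarray:
    """Log-spaced grid spanning [0.01, 1] * sqrt(log p / n)."""
    scale = np.sqrt(np.log(p) / n)
    return np.geomspace(0.01, 1.0, size) * scale


def bic_lambda2(sigma_A: np.ndarray, delta_hat: np.ndarray,
                lambda2_grid: Sequence[float], n: int,
                tol: float = 1e-6, max_iter: int = 2000
                ) -> Tuple[float, np.ndarray, List[Tuple[float, float]]]:
    """Select ``lambda2`` by a BIC-type criterion.

    For each candidate, the criterion is the fit part of the transfer
    objective plus ``(log n / n) ||Theta||_0`` where the zero-norm
    counts diagonal entries plus nonzero upper-triangle off-diagonals.
    Ties go to the larger (sparser) candidate.
    """
    grid = list(lambda2_grid)
    if not grid:
        raise ValueError("lambda2 grid is empty")
    trace: List[Tuple[float, float]] = []
    best = None
    last_error: Optional[Exception] = None
    for lam2 in grid:
        try:
            theta = solve_theta(sigma_A, delta_hat, lam2, tol=tol,
                                max_iter=max_iter)
        except SolverConvergenceError as exc:
            logger.warning("lambda2=%g failed: %s", lam2, exc)
            last_error = exc
            continue
        p = theta.shape[0]
        iu = np.triu_indices(p, k=1)
        nnz = p + int(np.sum(np.abs(theta[iu]) > _ZERO_TOL))
        fit_part = float(0.5 * np.sum(theta * (sigma_A @ theta)) -
                         np.sum((np.asarray(delta_hat).T + np.eye(p)) * theta))
        crit = fit_part + (np.log(n) / n) * nnz
        trace.append((float(lam2), crit))
        if best is None or crit <= best[0] + 1e-9:
            best = (crit, float(lam2), theta)
    if best is None:
        raise RuntimeError("every lambda2 candidate failed") from last_error
    return best[1], best[2], trace


def local_transfer(target_fit: GGMMResults,
                   aux_fits: Dict[int, GGMMResults],
                   aux_data: Dict[int, SampleMatrix],
                   config: Optional[TransferConfig] = None
                   ) -> List[TransferResult]:
    """Run prescreening, weighting and transfer for every target subgroup.

    Returns one :class:`TransferResult` per target subgroup, in order.
    Subgroups with an empty informative set keep their initial precision
    exactly (negative-transfer safeguard); with no auxiliary domains at
    all, every subgroup falls back this way.
    """
    cfg = config if config is not None else TransferConfig()
    p = target_fit.data.p
    n = target_fit.data.n
    # pseudo covariances of every auxiliary subgroup, shared across target l
    pcs: Dict[Tuple[int, int], PseudoCovariance] = {}
    mus_aux: Dict[Tuple[int, int], np.ndarray] = {}
    for k, fit in aux_fits.items():
        if fit.data.p != p:
            raise ValueError(f"auxiliary domain {k} has p={fit.data.p}, "
                             f"target has p={p}")
        data_k = aux_data[k]
        for lp, g in enumerate(fit.subgroups):
            pc = pseudo_covariance(data_k, fit.gamma[:, lp], g.mu,
                                   domain_id=k, subgroup_id=lp)
            pcs[(k, lp)] = pc
            mus_aux[(k, lp)] = g.mu
    results: List[TransferResult] = []
    grid = (cfg.lambda2_grid if cfg.lambda2_grid is not None
            else default_lambda2_grid(p, n))
    for l, g in enumerate(target_fit.subgroups):
        theta0 = g.theta
        records = [
            divergence(theta0, pcs[src], g.mu, mus_aux[src],
                       target_subgroup=l)
            for src in pcs
        ]
        lam1 = lambda1_rule(theta0, p, n)
        iset = prescreen(records, theta0, target_fit.pseudo_sizes[l], p,
                         c=cfg.c, target_subgroup=l, denoise_level=lam1)
        if not iset.members:
            logger.info("subgroup %d: informative set empty "
                        "(threshold %.4f) -> no transfer", l, iset.threshold)
            results.append(TransferResult(
                target_subgroup=l, transferred=False,
                theta_hat=theta0.copy(), informative_set=iset))
            continue
        weights = adaptive_weights(
            iset, records, {src: pcs[src].n_pseudo for src in iset.members},
            denoise_level=lam1)
        sigma_A = aggregate_covariance(weights, pcs)
        delta_hat = threshold_delta(theta0, sigma_A, lam1)
        lam2, theta_hat, trace = bic_lambda2(sigma_A, delta_hat, grid, n,
                                             tol=cfg.cd_tol,
                                             max_iter=cfg.cd_max_iter)
        logger.info("subgroup %d: transfer from %d source(s) "
                    "(threshold %.4f, lambda1 %.4f, lambda2 %.4f)",
                    l, len(iset.members), iset.threshold, lam1, lam2)
        results.append(TransferResult(
            target_subgroup=l, transferred=True, theta_hat=theta_hat,
            delta_hat=delta_hat, sigma_A=sigma_A, lambda1=float(lam1),
            lambda2=float(lam2), bic_trace=trace, informative_set=iset,
            weights=weights))
    return results


@dataclass
class LocalTransferResults:
    """Container for per-subgroup transfer outcomes."""

    results: List[TransferResult]
    target_fit: GGMMResults

    @property
    def precisions(self) -> List[np.ndarray]:
        return [r.theta_hat for r in self.results]

    @property
    def transferred(self) -> List[bool]:
        return [r.transferred for r in self.results]

    def summary(self) -> str:
        lines = [
            "Local transfer results",
            "=" * 58,
            f"target domain: n = {self.target_fit.data.n}, "
            f"p = {self.target_fit.data.p}, "
            f"L_hat = {self.target_fit.L_hat}",
            "-" * 58,
            f"{'subgroup':>8} {'transferred':>12} {'sources':>8} "
            f"{'lambda1':>9} {'lambda2':>9} {'edges':>7}",
        ]
        for r in self.results:
            iu = np.triu_indices(r.theta_hat.shape[0], k=1)
            edges = int(np.sum(np.abs(r.theta_hat[iu]) > _ZERO_TOL))
            nsrc = len(r.informative_set.members) if r.informative_set else 0
            lam1 = f"{r.lambda1:.4f}" if r.lambda1 is not None else "-"
            lam2 = f"{r.lambda2:.4f}" if r.lambda2 is not None else "-"
            lines.append(f"{r.target_subgroup:>8} {str(r.transferred):>12} "
                         f"{nsrc:>8} {lam1:>9} {lam2:>9} {edges:>7}")
        return "\n".join(lines)


class LocalTransfer:
    """Transfer model over a fitted target domain and auxiliary fits.

    Parameters
    ----------
    target_results : GGMMResults
        Initialization-stage fit of the target domain.
    aux_results : dict int -> GGMMResults
        Initialization fits of the auxiliary domains.
    aux_data : dict int -> SampleMatrix
        The auxiliary data the fits were computed on.
    config : TransferConfig, optional
        Prescreening constant and tuning grids; keyword arguments
        override individual fields.
    """

    def __init__(self, target_results: GGMMResults,
                 aux_results: Dict[int, GGMMResults],
                 aux_data: Dict[int, SampleMatrix],
                 config: Optional[TransferConfig] = None, **kwargs):
        cfg = config if config is not None else TransferConfig()
        if kwargs:
            cfg = TransferConfig(**{**cfg.__dict__, **kwargs})
        self.target_results = target_results
        self.aux_results = dict(aux_results)
        self.aux_data = dict(aux_data)
        self.config = cfg

    def fit(self) -> LocalTransferResults:
        results = local_transfer(self.target_results, self.aux_results,
                                 self.aux_data, self.config)
        return LocalTransferResults(results=results,
                                    target_fit=self.target_results)
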