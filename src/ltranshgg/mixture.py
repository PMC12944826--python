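"""Penalized EM for sparse Gaussian graphical mixtures with unknown L.

The initialization stage of the transfer pipeline fits, to each domain
separately, a Gaussian graphical mixture with an l1 (sparsity) penalty
on every precision matrix and a concave (MCP) fusion penalty on pairwise
differences of stacked subgroup parameters.  Starting from ``L_max``
k-means clusters, nearby components are gradually shrunk together and
merged as the fusion weight grows, so the number of subgroups is
estimated from a solution path rather than fixed in advance.  An
"oracle" mode (``fixed_L``) skips fusion and fits a mixture with a known
component count.

Model selection along the path uses a BIC with degrees of freedom
counting the subgroup means, precision diagonals, nonzero off-diagonal
precision entries (upper triangle), and the free mixing proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import (SampleMatrix, SubgroupParams, observed_loglik,
                   pseudo_covariance, responsibilities)
from .glasso import refit_support, weighted_graphical_lasso

logger = logging.getLogger(__name__)

__all__ = [
    "EMConfig",
    "GGMMResults",
    "SolutionPath",
    "PathEntry",
    "GraphicalGaussianMixture",
    "default_lambda_sparsity",
    "penalized_em_fit",
    "fit_solution_path",
    "select_fit",
    "bic_score",
]

_ZERO_TOL = 1e-8


def default_lambda_sparsity(n: int, p: int) -> float:
    """Default base l1 weight ``sqrt(log p / n)``.

    The effective per-component penalty is ``lambda_sparsity / pi_l``,
    i.e. about ``L * sqrt(log p / n)`` for balanced subgroups — the
    usual single-task graphical-lasso rate at the subgroup sample size.
    """
    return float(np.sqrt(np.log(p) / n))


@dataclass
class EMConfig:
    """Tuning knobs of the penalized EM.

    Parameters
    ----------
    L_max : int
        Upper bound on the number of components (start of the path).
    lambda_sparsity : float, optional
        Base l1 penalty on off-diagonal precision entries; the component
        penalty is ``lambda_sparsity / pi_l``.  ``None`` selects
        ``2 sqrt(log p / n)``.
    lambda_fusion_grid : sequence of float, optional
        Increasing fusion weights for the solution path; ``None`` builds
        a data-driven grid from the unfused fit.
    max_iter, tol : int, float
        EM iteration cap and relative objective-change threshold.
    merge_eps : float
        Components whose stacked parameter distance
        ``||mu_a - mu_b||_2 + ||Theta_a - Theta_b||_F`` falls below this
        are merged.
    seed : int
        Seed for the k-means initialization.
    fixed_L : int, optional
        Oracle mode: fit exactly this many components, no fusion path.
    kmeans_restarts : int
        Restarts of the k-means initializer; best inertia kept.
    mcp_a : float
        Concavity constant of the MCP fusion penalty.
    refit : bool
        After convergence, replace each precision by the
        support-constrained Gaussian MLE on its selected sparsity
        pattern (two-stage debiasing); the support, hence the selected
        edges, is unchanged.
    """

    L_max: int = 6
    lambda_sparsity: Optional[float] = None
    lambda_fusion_grid: Optional[Sequence[float]] = None
    max_iter: int = 200
    tol: float = 1e-5
    merge_eps: float = 1e-3
    seed: int = 0
    fixed_L: Optional[int] = None
    kmeans_restarts: int = 10
    mcp_a: float = 3.0
    refit: bool = True

    def __post_init__(self) -> None:
        if self.L_max < 1:
            raise ValueError("L_max must be >= 1")
        if self.tol <= 0 or self.merge_eps <= 0:
            raise ValueError("tol and merge_eps must be positive")
        if self.lambda_sparsity is not None and self.lambda_sparsity < 0:
            raise ValueError("lambda_sparsity must be nonnegative")
        if self.lambda_fusion_grid is not None:
            grid = list(self.lambda_fusion_grid)
            if any(g < 0 for g in grid) or grid != sorted(grid):
                raise ValueError("lambda_fusion_grid must be increasing "
                                 "and nonnegative")
            self.lambda_fusion_grid = grid


@dataclass
class GGMMResults:
    """A fitted Gaussian graphical mixture for one domain.

    Attributes
    ----------
    subgroups : list of SubgroupParams
        Estimated (pi, mu, Theta) per subgroup.
    gamma : (n, L_hat) ndarray
        Final E-step responsibilities; rows sum to one.
    pseudo_sizes : (L_hat,) ndarray
        Column sums of ``gamma`` (effective subgroup sample sizes).
    lambda_used : dict
        Penalty values the fit was run with.
    objective_trace : list of float
        Penalized objective per EM iteration (non-increasing).
    """

    subgroups: List[SubgroupParams]
    gamma: np.ndarray
    pseudo_sizes: np.ndarray
    lambda_used: dict
    objective_trace: List[float]
    loglik: float
    n_iter: int
    converged: bool
    data: SampleMatrix = field(repr=False)

    @property
    def L_hat(self) -> int:
        return len(self.subgroups)

    @property
    def labels(self) -> np.ndarray:
        """Hard subgroup assignment (argmax responsibility)."""
        return np.argmax(self.gamma, axis=1)

    @property
    def means(self) -> List[np.ndarray]:
        return [g.mu for g in self.subgroups]

    @property
    def precisions(self) -> List[np.ndarray]:
        return [g.theta for g in self.subgroups]

    @property
    def proportions(self) -> np.ndarray:
        return np.array([g.pi for g in self.subgroups])

    def bic(self) -> float:
        return bic_score(self)

    def summary(self) -> str:
        lines = [
            "Gaussian graphical mixture fit",
            "=" * 46,
            f"domain: {self.data.domain_id}   n = {self.data.n}   "
            f"p = {self.data.p}",
            f"subgroups (L_hat): {self.L_hat}   converged: {self.converged} "
            f"({self.n_iter} iterations)",
            f"log-likelihood: {self.loglik:.3f}   BIC: {self.bic():.3f}",
            "-" * 46,
            f"{'subgroup':>8} {'pi':>8} {'n_pseudo':>10} {'edges':>7}",
        ]
        for l, g in enumerate(self.subgroups):
            iu = np.triu_indices(g.p, k=1)
            edges = int(np.sum(np.abs(g.theta[iu]) > _ZERO_TOL))
            lines.append(f"{l:>8} {g.pi:>8.4f} "
                         f"{self.pseudo_sizes[l]:>10.1f} {edges:>7}")
        return "\n".join(lines)


@dataclass
class PathEntry:
    lambda_fusion: float
    L_hat: int
    bic_value: float
    fit: Optional[GGMMResults]
    error: Optional[str] = None


@dataclass
class SolutionPath:
    """Fits along an increasing fusion-penalty grid."""

    entries: List[PathEntry]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def bic_score(fit: GGMMResults) -> float:
    """BIC = -2 loglik + log(n) df.

    df counts L*p mean entries, L*p precision diagonals, the nonzero
    upper-triangle off-diagonals of every precision, and L - 1 free
    mixing proportions.
    """
    n = fit.data.n
    p = fit.data.p
    L = fit.L_hat
    nnz = 0
    iu = np.triu_indices(p, k=1)
    for g in fit.subgroups:
        nnz += int(np.sum(np.abs(g.theta[iu]) > _ZERO_TOL))
    df = 2 * L * p + nnz + (L - 1)
    return -2.0 * fit.loglik + np.log(n) * df


def _mcp_penalty(t: float, lam: float, a: float) -> float:
    if t <= a * lam:
        return lam * t - t * t / (2.0 * a)
    return a * lam * lam / 2.0


def _mcp_prox(d: np.ndarray, lam: float, a: float) -> np.ndarray:
    """Group MCP proximal shrinkage of a difference vector (unit step)."""
    norm = float(np.linalg.norm(d))
    if norm == 0.0 or lam == 0.0 or norm > a * lam:
        return d
    factor = max(0.0, 1.0 - lam / norm) / (1.0 - 1.0 / a)
    return d * min(factor, 1.0)


@dataclass
class _State:
    """Mutable EM state (parameters + responsibilities)."""

    pis: np.ndarray
    mus: List[np.ndarray]
    thetas: List[np.ndarray]
    gamma: np.ndarray

    def copy(self) -> "_State":
        return _State(self.pis.copy(), [m.copy() for m in self.mus],
                      [t.copy() for t in self.thetas], self.gamma.copy())

    @property
    def L(self) -> int:
        return len(self.mus)

    def subgroups(self) -> List[SubgroupParams]:
        return [SubgroupParams(pi=float(p), mu=m, theta=t)
                for p, m, t in zip(self.pis, self.mus, self.thetas)]


def _ensure_pd(theta: np.ndarray) -> np.ndarray:
    theta = 0.5 * (theta + theta.T)
    smallest = float(np.linalg.eigvalsh(theta)[0])
    if smallest <= 1e-8:
        theta = theta + (1e-6 - smallest) * np.eye(theta.shape[0])
    return theta


def _objective(data: SampleMatrix, state: _State, lam_s: float,
               lam_f: float, mcp_a: float) -> float:
    """Penalized objective: -loglik + n lam_s sum ||Theta||_1,off
    + n lam_f sum_pairs MCP(||v_a - v_b||)."""
    n = data.n
    obj = -observed_loglik(data, state.subgroups())
    iu = np.triu_indices(data.p, k=1)
    for theta in state.thetas:
        obj += n * lam_s * 2.0 * float(np.sum(np.abs(theta[iu])))
    if lam_f > 0 and state.L > 1:
        vs = [np.concatenate([m, t.ravel()])
              for m, t in zip(state.mus, state.thetas)]
        for a in range(state.L):
            for b in range(a + 1, state.L):
                obj += n * _mcp_penalty(
                    float(np.linalg.norm(vs[a] - vs[b])), lam_f, mcp_a)
    return obj


def _e_step(data: SampleMatrix, state: _State) -> _State:
    state.gamma = responsibilities(data, state.subgroups())
    return state


def _drop_empty(state: _State, min_size: float = 1.0) -> _State:
    sizes = state.gamma.sum(axis=0)
    keep = sizes >= min_size
    if keep.all():
        return state
    if not keep.any():
        raise RuntimeError("all mixture components collapsed")
    logger.warning("dropping %d collapsed component(s) with pseudo size < %g",
                   int((~keep).sum()), min_size)
    gamma = state.gamma[:, keep]
    gamma = gamma / gamma.sum(axis=1, keepdims=True)
    pis = state.pis[keep]
    pis = pis / pis.sum()
    return _State(pis, [m for m, k in zip(state.mus, keep) if k],
                  [t for t, k in zip(state.thetas, keep) if k], gamma)


def _m_step(data: SampleMatrix, state: _State, lam_s: float,
            lam_f: float, mcp_a: float, apply_fusion: bool) -> _State:
    n, p = data.n, data.p
    sizes = state.gamma.sum(axis=0)
    pis = sizes / n
    mus, thetas = [], []
    off = 1.0 - np.eye(p)
    for l in range(state.L):
        w = state.gamma[:, l]
        mu = (w @ data.values) / sizes[l]
        pc = pseudo_covariance(data, w, mu, data.domain_id, l)
        penalty = (lam_s / max(pis[l], 1e-12)) * off
        theta = weighted_graphical_lasso(pc.sigma_tilde, penalty,
                                         init=state.thetas[l])
        mus.append(mu)
        thetas.append(theta)
    if apply_fusion and lam_f > 0 and state.L > 1:
        vs = [np.concatenate([m, t.ravel()]) for m, t in zip(mus, thetas)]
        for a in range(len(vs)):
            for b in range(a + 1, len(vs)):
                d = vs[a] - vs[b]
                shrunk = _mcp_prox(d, lam_f, mcp_a)
                shift = 0.5 * (d - shrunk)
                vs[a] = vs[a] - shift
                vs[b] = vs[b] + shift
        mus = [v[:p].copy() for v in vs]
        thetas = [_ensure_pd(v[p:].reshape(p, p)) for v in vs]
    return _State(np.asarray(pis), mus, thetas, state.gamma)


def _merge_close(state: _State, merge_eps: float) -> _State:
    """Hard-merge components whose parameter distance is below merge_eps."""
    changed = True
    while changed and state.L > 1:
        changed = False
        for a in range(state.L):
            for b in range(a + 1, state.L):
                dist = (np.linalg.norm(state.mus[a] - state.mus[b]) +
                        np.linalg.norm(state.thetas[a] - state.thetas[b]))
                if dist < merge_eps:
                    wa, wb = state.pis[a], state.pis[b]
                    wsum = wa + wb
                    mu = (wa * state.mus[a] + wb * state.mus[b]) / wsum
                    theta = _ensure_pd(
                        (wa * state.thetas[a] + wb * state.thetas[b]) / wsum)
                    gamma = np.delete(state.gamma, b, axis=1)
                    gamma[:, a] = state.gamma[:, a] + state.gamma[:, b]
                    pis = np.delete(state.pis, b)
                    pis[a] = wsum
                    mus = [m for i, m in enumerate(state.mus) if i != b]
                    thetas = [t for i, t in enumerate(state.thetas) if i != b]
                    mus[a] = mu
                    thetas[a] = theta
                    state = _State(pis, mus, thetas, gamma)
                    changed = True
                    break
            if changed:
                break
    return state


def _kmeans_init(data: SampleMatrix, L: int, config: EMConfig,
                 lam_s: float) -> _State:
    km = KMeans(n_clusters=L, n_init=config.kmeans_restarts,
                random_state=config.seed)
    labels = km.fit_predict(data.values)
    n, p = data.n, data.p
    gamma = np.zeros((n, L))
    gamma[np.arange(n), labels] = 1.0
    # guard against empty k-means clusters (possible for poor L choices)
    sizes = gamma.sum(axis=0)
    keep = sizes >= 2
    gamma = gamma[:, keep]
    L = gamma.shape[1]
    sizes = gamma.sum(axis=0)
    pis = sizes / n
    off = 1.0 - np.eye(p)
    mus, thetas = [], []
    for l in range(L):
        w = gamma[:, l]
        mu = (w @ data.values) / sizes[l]
        pc = pseudo_covariance(data, w, mu, data.domain_id, l)
        penalty = (lam_s / max(pis[l], 1e-12)) * off
        thetas.append(weighted_graphical_lasso(pc.sigma_tilde, penalty))
        mus.append(mu)
    return _State(pis, mus, thetas, gamma)


def penalized_em_fit(data: SampleMatrix, config: EMConfig,
                     lambda_fusion: float = 0.0,
                     init_state: Optional[_State] = None) -> GGMMResults:
    """One penalized-EM fit at a fixed fusion weight.

    Initializes from seeded k-means (or a warm start), then alternates
    E-steps with M-steps consisting of weighted means, per-component
    weighted graphical lasso precision updates, a single MCP fusion
    shrinkage pass over stacked (mu, vec(Theta)) pairs, and hard merging
    of components closer than ``merge_eps``.  An acceptance check keeps
    the penalized objective non-increasing: if a fused update would
    raise it the unfused update is used, and if that also raises it the
    iteration terminates.
    """
    lam_s = (config.lambda_sparsity if config.lambda_sparsity is not None
             else default_lambda_sparsity(data.n, data.p))
    L0 = config.fixed_L if config.fixed_L is not None else config.L_max
    if data.n <= L0:
        raise ValueError("need more samples than components")
    if init_state is not None:
        state = init_state.copy()
    else:
        state = _kmeans_init(data, L0, config, lam_s)
    state = _e_step(data, state)
    obj = _objective(data, state, lam_s, lambda_fusion, config.mcp_a)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        state = _drop_empty(state)
        accepted = None
        for apply_fusion in ((True, False) if lambda_fusion > 0 else (False,)):
            cand = _m_step(data, state, lam_s, lambda_fusion, config.mcp_a,
                           apply_fusion)
            cand = _merge_close(cand, config.merge_eps)
            cand = _e_step(data, cand)
            cand_obj = _objective(data, cand, lam_s, lambda_fusion,
                                  config.mcp_a)
            if cand_obj <= obj + 1e-6 * (1.0 + abs(obj)):
                accepted = (cand, cand_obj)
                break
        if accepted is None:
            converged = True
            break
        state, new_obj = accepted
        trace.append(new_obj)
        if abs(obj - new_obj) <= config.tol * (1.0 + abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if config.refit:
        # two-stage debiasing: support-constrained MLE per component on
        # the final pseudo covariances; the selected support is kept
        state = _e_step(data, state)
        sizes = state.gamma.sum(axis=0)
        for l in range(state.L):
            w = state.gamma[:, l]
            mu = (w @ data.values) / sizes[l]
            pc = pseudo_covariance(data, w, mu, data.domain_id, l)
            support = np.abs(state.thetas[l]) > _ZERO_TOL
            try:
                state.thetas[l] = refit_support(pc.sigma_tilde, support)
                state.mus[l] = mu
            except Exception as exc:  # keep the penalized estimate
                logger.warning("refit of component %d failed (%s); "
                               "keeping penalized estimate", l, exc)
    state = _e_step(data, state)
    subgroups = state.subgroups()
    return GGMMResults(
        subgroups=subgroups,
        gamma=state.gamma,
        pseudo_sizes=state.gamma.sum(axis=0),
        lambda_used={"lambda_sparsity": lam_s,
                     "lambda_fusion": lambda_fusion},
        objective_trace=trace,
        loglik=observed_loglik(data, subgroups),
        n_iter=it,
        converged=converged,
        data=data,
    )


def _auto_fusion_grid(fit: GGMMResults, n_points: int = 8) -> List[float]:
    """Fusion grid spanning zero to past the largest parameter gap."""
    if fit.L_hat < 2:
        return [0.0]
    vs = [np.concatenate([g.mu, g.theta.ravel()]) for g in fit.subgroups]
    dmax = max(np.linalg.norm(vs[a] - vs[b])
               for a in range(len(vs)) for b in range(a + 1, len(vs)))
    grid = np.geomspace(0.02 * dmax, 1.5 * dmax, n_points)
    return [0.0] + [float(g) for g in grid]


def fit_solution_path(data: SampleMatrix, config: EMConfig) -> SolutionPath:
    """Fits along the fusion grid with warm starts from the previous fit.

    Because each fit starts from the previous (already partially merged)
    parameters and EM never splits components, the estimated subgroup
    number is non-increasing along the path.
    """
    if config.lambda_fusion_grid is not None:
        grid = list(config.lambda_fusion_grid)
        if not grid:
            raise ValueError("lambda_fusion_grid must be nonempty")
        base = penalized_em_fit(data, config, lambda_fusion=grid[0])
        entries = [PathEntry(grid[0], base.L_hat, bic_score(base), base)]
        rest = grid[1:]
    else:
        base = penalized_em_fit(data, config, lambda_fusion=0.0)
        grid = _auto_fusion_grid(base)
        entries = [PathEntry(0.0, base.L_hat, bic_score(base), base)]
        rest = grid[1:]
    prev = base
    for lam_f in rest:
        warm = _State(prev.proportions.copy(),
                      [g.mu.copy() for g in prev.subgroups],
                      [g.theta.copy() for g in prev.subgroups],
                      prev.gamma.copy())
        try:
            fit = penalized_em_fit(data, config, lambda_fusion=lam_f,
                                   init_state=warm)
        except Exception as exc:  # record failure, keep going
            logger.warning("path entry lambda_fusion=%g failed: %s",
                           lam_f, exc)
            entries.append(PathEntry(lam_f, -1, np.inf, None, error=str(exc)))
            continue
        entries.append(PathEntry(lam_f, fit.L_hat, bic_score(fit), fit))
        prev = fit
    return SolutionPath(entries=entries)


def select_fit(path: SolutionPath) -> GGMMResults:
    """Entry with minimal BIC; ties broken toward fewer subgroups."""
    best: Optional[PathEntry] = None
    for entry in path:
        if entry.fit is None:
            continue
        if best is None:
            best = entry
            continue
        if (entry.bic_value < best.bic_value - 1e-9 or
                (abs(entry.bic_value - best.bic_value) <= 1e-9 and
                 entry.L_hat < best.L_hat)):
            best = entry
    if best is None:
        raise RuntimeError("every solution-path entry failed")
    return best.fit


class GraphicalGaussianMixture:
    """Sparse Gaussian graphical mixture model for one domain.

    Parameters
    ----------
    data : SampleMatrix or ndarray or DataFrame
        The n x p sample-by-feature matrix of the domain.
    config : EMConfig, optional
        Tuning parameters; keyword arguments override individual fields.

    Examples
    --------
    >>> model = GraphicalGaussianMixture(X, fixed_L=3, seed=1)
    >>> res = model.fit()
    >>> res.L_hat
    3
    """

    def __init__(self, data, config: Optional[EMConfig] = None, **kwargs):
        if isinstance(data, SampleMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = SampleMatrix(values=data.to_numpy(dtype=float),
                                     feature_names=list(data.columns))
        else:
            self.data = SampleMatrix(values=np.asarray(data, dtype=float))
        cfg = config if config is not None else EMConfig()
        if kwargs:
            cfg = EMConfig(**{**cfg.__dict__, **kwargs})
        self.config = cfg

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, domain_id: str = "target",
                       **kwargs) -> "GraphicalGaussianMixture":
        data = SampleMatrix(values=df.to_numpy(dtype=float),
                            domain_id=domain_id,
                            feature_names=list(df.columns))
        return cls(data, **kwargs)

    def fit(self, lambda_fusion: float = 0.0) -> GGMMResults:
        """Single penalized-EM fit at the given fusion weight."""
        return penalized_em_fit(self.data, self.config, lambda_fusion)

    def fit_path(self) -> SolutionPath:
        """Full fusion solution path."""
        return fit_solution_path(self.data, self.config)

    def fit_select(self) -> GGMMResults:
        """Fit the path (or oracle mode) and return the selected fit."""
        if self.config.fixed_L is not None:
            return self.fit()
        return select_fit(self.fit_path())
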