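"""Benchmark metrics for subgrouping and network recovery.

Covers the clustering (subgrouping) error CE, alignment of estimated to
true subgroups, mean-squared errors of subgroup means and precision
matrices, off-diagonal support recovery rates, and aggregation over
simulation replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MetricsReport",
    "ReplicationSummary",
    "clustering_error",
    "match_subgroups",
    "mse_params",
    "support_rates",
    "summarize_replications",
]

_ZERO_TOL = 1e-8


@dataclass
class MetricsReport:
    """Per-replication metrics for one fitted model."""

    L_hat: int
    CE: float
    mse_mean: float
    mse_precision: float
    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.CE <= 1.0:
            raise ValueError("CE must lie in [0, 1]")
        for name in ("tpr", "fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ReplicationSummary:
    """Replication-averaged metrics (means and sample SDs)."""

    per: float
    L_mean: float
    L_sd: float
    means: Dict[str, float] = field(default_factory=dict)
    sds: Dict[str, float] = field(default_factory=dict)


def clustering_error(labels_est: np.ndarray, labels_true: np.ndarray) -> float:
    """Pairwise subgrouping error CE.

    The fraction of unordered sample pairs on which the estimated and
    true co-membership indicators disagree; invariant under relabeling
    of either partition.  Computed from the contingency table in
    O(n + G^2) rather than by enumerating pairs: with ``N`` the
    contingency table, row sums ``a`` and column sums ``b``, the number
    of disagreeing pairs is
    ``sum C(a_i,2) + sum C(b_j,2) - 2 sum C(N_ij,2)``.
    """
    labels_est = np.asarray(labels_est).ravel()
    labels_true = np.asarray(labels_true).ravel()
    if labels_est.shape != labels_true.shape:
        raise ValueError("label vectors must have equal length")
    n = labels_est.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    _, ti = np.unique(labels_true, return_inverse=True)
    _, ei = np.unique(labels_est, return_inverse=True)
    table = np.zeros((ti.max() + 1, ei.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, ei), 1)

    def pairs(x: np.ndarray) -> int:
        return int(np.sum(x * (x - 1) // 2))

    same_true = pairs(table.sum(axis=1))
    same_est = pairs(table.sum(axis=0))
    same_both = pairs(table)
    disagreements = same_true + same_est - 2 * same_both
    return disagreements / (n * (n - 1) // 2)


def _as_labels(gamma_or_labels: np.ndarray) -> np.ndarray:
    arr = np.asarray(gamma_or_labels)
    if arr.ndim == 2:
        return np.argmax(arr, axis=1)
    return arr.ravel()


def match_subgroups(est: np.ndarray, truth: np.ndarray) -> Dict[int, int]:
    """Align true subgroups with estimated ones by membership overlap.

    Uses the Hungarian algorithm to maximize total overlap on
    ``min(L, L_hat)`` one-to-one pairs.  When fewer subgroups were
    estimated than exist (``L_hat < L``), each unmatched true subgroup
    maps to its maximum-overlap estimated subgroup (many-to-one).
    Surplus estimated subgroups are ignored.  Keys/values are indices
    into the sorted unique labels of each partition.
    """
    est_labels = _as_labels(est)
    true_labels = _as_labels(truth)
    if est_labels.shape != true_labels.shape:
        raise ValueError("label vectors must have equal length")
    true_ids, ti = np.unique(true_labels, return_inverse=True)
    est_ids, ei = np.unique(est_labels, return_inverse=True)
    overlap = np.zeros((len(true_ids), len(est_ids)), dtype=np.int64)
    np.add.at(overlap, (ti, ei), 1)
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {int(r): int(c) for r, c in zip(rows, cols)}
    for l in range(len(true_ids)):
        if l not in mapping:
            mapping[l] = int(np.argmax(overlap[l]))
    return mapping


def mse_params(est_means: Sequence[np.ndarray],
               est_precisions: Sequence[np.ndarray],
               true_means: Sequence[np.ndarray],
               true_precisions: Sequence[np.ndarray],
               matching: Dict[int, int]) -> Tuple[float, float]:
    """Average squared errors of means (l2^2) and precisions (Frobenius^2).

    Errors are averaged over the true subgroups through ``matching``
    without normalization by dimension, so values scale with ``p``.
    """
    L = len(true_means)
    if set(matching.keys()) < set(range(L)):
        raise ValueError("matching must cover every true subgroup")
    mse_mu = 0.0
    mse_theta = 0.0
    for l in range(L):
        m = matching[l]
        dmu = np.asarray(est_means[m]) - np.asarray(true_means[l])
        dth = np.asarray(est_precisions[m]) - np.asarray(true_precisions[l])
        if dmu.shape != np.asarray(true_means[l]).shape or \
                dth.shape != np.asarray(true_precisions[l]).shape:
            raise ValueError("dimension mismatch between estimate and truth")
        mse_mu += float(dmu @ dmu)
        mse_theta += float(np.sum(dth * dth))
    return mse_mu / L, mse_theta / L


def support_rates(est_precisions: Sequence[np.ndarray],
                  true_precisions: Sequence[np.ndarray],
                  matching: Dict[int, int]) -> Tuple[float, float]:
    """Average off-diagonal TPR and FPR of the precision supports.

    Per true subgroup, on strict upper-triangle entries: TPR is the
    fraction of true edges recovered, FPR the fraction of true
    non-edges declared edges (zero tolerance 1e-8), both averaged over
    subgroups.
    """
    L = len(true_precisions)
    if set(matching.keys()) < set(range(L)):
        raise ValueError("matching must cover every true subgroup")
    tprs, fprs = [], []
    for l in range(L):
        true_theta = np.asarray(true_precisions[l])
        est_theta = np.asarray(est_precisions[matching[l]])
        iu = np.triu_indices_from(true_theta, k=1)
        true_edge = np.abs(true_theta[iu]) > _ZERO_TOL
        est_edge = np.abs(est_theta[iu]) > _ZERO_TOL
        n_true = int(true_edge.sum())
        if n_true == 0:
            raise ValueError(
                f"true subgroup {l} has no off-diagonal edges; exclude it "
                "from support-rate evaluation")
        n_null = true_edge.size - n_true
        tprs.append(float((true_edge & est_edge).sum()) / n_true)
        fprs.append(float((~true_edge & est_edge).sum()) / n_null
                    if n_null > 0 else 0.0)
    return float(np.mean(tprs)), float(np.mean(fprs))


def summarize_replications(reports: Sequence[MetricsReport],
                           true_L: int) -> ReplicationSummary:
    """Aggregate per-replication metrics as in a simulation table.

    ``per`` is the fraction of replications that estimated the true
    subgroup number; SDs use denominator ``n - 1`` and are reported as
    zero for a single replication.
    """
    if not reports:
        raise ValueError("no reports to summarize")
    fields = ("CE", "mse_mean", "mse_precision", "tpr", "fpr")
    L_hats = np.array([r.L_hat for r in reports], dtype=float)

    def sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    means = {}
    sds = {}
    for name in fields:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        means[name] = float(vals.mean())
        sds[name] = sd(vals)
    return ReplicationSummary(
        per=float(np.mean(L_hats == true_L)),
        L_mean=float(L_hats.mean()),
        L_sd=sd(L_hats),
        means=means,
        sds=sds,
    )
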