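"""Synthetic multi-domain GGMM data.

Generates target + auxiliary domains for benchmarking subgroup-level
transfer of precision matrices.  Two canonical designs are provided:

* **Example 1 (overall similarity)** — five auxiliary domains, each with
  the same three subgroups as the target; the first ``card_A`` domains
  are informative (every subgroup is a small perturbation of the
  corresponding target subgroup), the rest are unrelated.
* **Example 2 (local similarity)** — six auxiliary domains with subgroup
  counts (2, 3, 4, 3, 3, 3); only the k-th subgroup of the k-th domain
  (k = 1, 2, 3) is informative for the k-th target subgroup, so each
  target subgroup has exactly one informative source hidden among many
  unrelated ones.

Subgroup networks are either tridiagonal (banded) precision matrices or
block power-law networks built from preferential-attachment graphs.
Informative auxiliary subgroups perturb a few off-diagonal entries of
the target precision and shift the mean slightly; non-informative
subgroups get freshly generated networks on a different precision scale
and distant means, so their divergence from every target subgroup is
large by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .core import SampleMatrix, SubgroupParams

__all__ = [
    "NetworkSpec",
    "DomainSpec",
    "SimTruth",
    "tridiagonal_precision",
    "block_power_law_precision",
    "network_precision",
    "perturb_informative",
    "sample_subgroup",
    "generate_target",
    "generate_example1",
    "generate_example2",
]

#: minimum admissible smallest eigenvalue of a generated precision matrix
_PD_FLOOR = 1e-6

#: per-subgroup sign patterns giving mutually divergent tridiagonal
#: variants: constant, sign-flipped, and alternating-sign bands
_BAND_PATTERNS = ("const", "neg", "alt", "alt_neg", "half", "half_neg")

#: precision scale of non-informative subgroups (variance inflated 4x),
#: which pushes their divergence from any target subgroup far above the
#: prescreening threshold
_NONINF_SCALE = 0.25

#: per-coordinate spacing of target subgroup means: mu_l = (l - 1) * 0.8 * 1_p
_MEAN_STEP = 0.8


@dataclass
class NetworkSpec:
    """Recipe for one family of subgroup precision matrices.

    Parameters
    ----------
    kind : {"tridiagonal", "block_power_law"}
        Network family.
    p : int
        Number of features.
    band_value : float
        Off-diagonal band entry of the tridiagonal family; must satisfy
        ``|band_value| < 0.5`` so the unit-diagonal matrix stays PD.
    block_size, attach_edges : int
        Power-law blocks: each independent block of ``block_size`` nodes
        carries a preferential-attachment graph adding ``attach_edges``
        edges per incoming node.
    edge_magnitude : float
        Absolute value of supported off-diagonal entries in power-law
        blocks (random sign).
    seed : int
        Base seed; variants derive their own streams from it.
    """

    kind: str = "tridiagonal"
    p: int = 100
    band_value: float = 0.3
    block_size: int = 20
    attach_edges: int = 1
    edge_magnitude: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("tridiagonal", "block_power_law"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if self.p < 2:
            raise ValueError("p must be >= 2")


@dataclass
class DomainSpec:
    """Layout of one auxiliary domain."""

    n_per_subgroup: int
    L: int
    informative_map: Dict[int, int] = field(default_factory=dict)
    perturb_entries: int = 10
    perturb_magnitude: float = 0.05

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if any(sg >= self.L or sg < 0 for sg in self.informative_map):
            raise ValueError("informative_map keys must index subgroups < L")


@dataclass
class SimTruth:
    """Ground truth of one simulated multi-domain data set.

    ``informative_sets`` maps each target subgroup index ``l`` to the set
    of (auxiliary domain index, auxiliary subgroup index) pairs whose
    parameters were generated as perturbations of target subgroup ``l``.
    All indices are 0-based.
    """

    target_params: List[SubgroupParams]
    aux_params: Dict[int, List[SubgroupParams]]
    memberships: Dict[str, np.ndarray]
    informative_sets: Dict[int, Set[Tuple[int, int]]]


def _check_pd(theta: np.ndarray, context: str) -> np.ndarray:
    smallest = float(np.linalg.eigvalsh(theta)[0])
    if smallest <= _PD_FLOOR:
        raise ValueError(
            f"{context}: generated precision is not PD "
            f"(smallest eigenvalue {smallest:.3e})"
        )
    return theta


def tridiagonal_precision(p: int, band_value) -> np.ndarray:
    """Unit-diagonal tridiagonal precision.

    ``band_value`` is either a scalar (constant band) or a length-(p-1)
    vector of band entries; every entry must satisfy ``|b| < 0.5`` so
    the matrix is strictly diagonally dominant, hence PD.
    """
    band = np.asarray(band_value, dtype=float) * np.ones(p - 1)
    if band.shape != (p - 1,):
        raise ValueError("band_value must be scalar or length p-1")
    if np.any(np.abs(band) >= 0.5):
        raise ValueError("|band_value| must be < 0.5 to guarantee PD")
    theta = np.eye(p)
    idx = np.arange(p - 1)
    theta[idx, idx + 1] = band
    theta[idx + 1, idx] = band
    return _check_pd(theta, "tridiagonal_precision")


def block_power_law_precision(p: int, block_size: int, attach_edges: int,
                              edge_magnitude: float, seed: int) -> np.ndarray:
    """Block-diagonal precision whose blocks follow power-law networks.

    Each block's support is a Barabasi-Albert preferential-attachment
    graph; supported entries get magnitude ``edge_magnitude`` with a
    random sign, and the diagonal is set to the row-wise absolute sum
    plus 0.1, making the matrix strictly diagonally dominant, hence PD.
    """
    if p % block_size != 0:
        raise ValueError("p must be divisible by block_size")
    rng = np.random.default_rng(seed)
    theta = np.zeros((p, p))
    for start in range(0, p, block_size):
        graph = nx.barabasi_albert_graph(
            block_size, attach_edges,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        block = np.zeros((block_size, block_size))
        for i, j in graph.edges():
            sign = 1.0 if rng.random() < 0.5 else -1.0
            block[i, j] = block[j, i] = sign * edge_magnitude
        np.fill_diagonal(block, np.abs(block).sum(axis=1) + 0.1)
        theta[start:start + block_size, start:start + block_size] = block
    return _check_pd(theta, "block_power_law_precision")


def network_precision(spec: NetworkSpec, variant: int = 0) -> np.ndarray:
    """One precision matrix from the family, distinct per ``variant``."""
    if spec.kind == "tridiagonal":
        pattern = _BAND_PATTERNS[variant % len(_BAND_PATTERNS)]
        b = spec.band_value
        alt = np.where(np.arange(spec.p - 1) % 2 == 0, 1.0, -1.0)
        band = {
            "const": b * np.ones(spec.p - 1),
            "neg": -b * np.ones(spec.p - 1),
            "alt": b * alt,
            "alt_neg": -b * alt,
            "half": 0.5 * b * np.ones(spec.p - 1),
            "half_neg": -0.5 * b * np.ones(spec.p - 1),
        }[pattern]
        return tridiagonal_precision(spec.p, band)
    return block_power_law_precision(
        spec.p, spec.block_size, spec.attach_edges, spec.edge_magnitude,
        seed=spec.seed * 1009 + 7919 * variant)


def perturb_informative(theta: np.ndarray, entries: int, magnitude: float,
                        seed: int) -> np.ndarray:
    """Perturb ``entries`` random symmetric off-diagonal pairs by +-magnitude.

    Positive definiteness is verified; if lost, the magnitude is halved
    and the perturbation redrawn, up to five times.
    """
    theta = np.asarray(theta, dtype=float)
    if entries == 0:
        return theta.copy()
    p = theta.shape[0]
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    mag = float(magnitude)
    for _ in range(5):
        chosen = rng.choice(len(pairs), size=min(entries, len(pairs)),
                            replace=False)
        out = theta.copy()
        for c in chosen:
            i, j = pairs[c]
            delta = mag if rng.random() < 0.5 else -mag
            out[i, j] += delta
            out[j, i] += delta
        if np.linalg.eigvalsh(out)[0] > _PD_FLOOR:
            return out
        mag *= 0.5
    raise ValueError("perturbation destroyed positive definiteness "
                     "even after halving the magnitude five times")


def sample_subgroup(n: int, mu: np.ndarray, theta: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` Gaussian samples with mean ``mu`` and precision ``theta``."""
    sigma = np.linalg.inv(theta)
    sigma = 0.5 * (sigma + sigma.T)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n, mu.shape[0]))
    return mu + z @ chol.T


def _target_mean(l: int, p: int) -> np.ndarray:
    return (l - 1) * _MEAN_STEP * np.ones(p)


def _informative_params(target: SubgroupParams, pi: float,
                        dspec: DomainSpec, seed: int) -> SubgroupParams:
    """A small perturbation of a target subgroup (informative source)."""
    rng = np.random.default_rng(seed)
    theta = perturb_informative(target.theta, dspec.perturb_entries,
                                dspec.perturb_magnitude,
                                seed=int(rng.integers(0, 2 ** 31 - 1)))
    shift = rng.uniform(-1.0, 1.0, size=target.p)
    l1 = np.abs(shift).sum()
    if l1 > 0:
        shift *= 0.5 * rng.uniform(0.5, 1.0) / l1  # l1 norm <= 0.5
    return SubgroupParams(pi=pi, mu=target.mu + shift, theta=theta)


def _noninformative_params(spec: NetworkSpec, pi: float,
                           target_means: Sequence[np.ndarray],
                           variant: int, seed: int) -> SubgroupParams:
    """An unrelated subgroup: rescaled fresh network, distant mean."""
    rng = np.random.default_rng(seed)
    fresh = NetworkSpec(kind=spec.kind, p=spec.p, band_value=spec.band_value,
                        block_size=spec.block_size,
                        attach_edges=spec.attach_edges,
                        edge_magnitude=spec.edge_magnitude,
                        seed=int(rng.integers(0, 2 ** 31 - 1)))
    theta = _NONINF_SCALE * network_precision(fresh, variant=variant)
    direction = rng.standard_normal(spec.p)
    direction /= np.linalg.norm(direction)
    anchor = target_means[int(rng.integers(0, len(target_means)))]
    mu = anchor + direction * rng.uniform(3.0, 5.0)
    return SubgroupParams(pi=pi, mu=mu, theta=theta)


def generate_target(spec: NetworkSpec, n0: int, seed: int,
                    L: int = 3) -> Tuple[SampleMatrix,
                                         List[SubgroupParams], np.ndarray]:
    """Target domain: ``L`` balanced subgroups of ``n0`` samples each.

    Subgroup means are equally spaced along the all-ones direction and
    each subgroup gets its own variant of the base network.
    """
    rng = np.random.default_rng(seed)
    params = [
        SubgroupParams(pi=1.0 / L, mu=_target_mean(l, spec.p),
                       theta=network_precision(spec, variant=l))
        for l in range(L)
    ]
    blocks, labels = [], []
    for l, g in enumerate(params):
        blocks.append(sample_subgroup(n0, g.mu, g.theta, rng))
        labels.append(np.full(n0, l))
    data = SampleMatrix(values=np.vstack(blocks), domain_id="target")
    return data, params, np.concatenate(labels)


def _generate_domain(spec: NetworkSpec, dspec: DomainSpec,
                     target_params: Sequence[SubgroupParams],
                     domain_index: int, seed: int
                     ) -> Tuple[SampleMatrix, List[SubgroupParams],
                                np.ndarray]:
    rng = np.random.default_rng(seed)
    target_means = [g.mu for g in target_params]
    params: List[SubgroupParams] = []
    for l in range(dspec.L):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        pi = 1.0 / dspec.L
        if l in dspec.informative_map:
            src = target_params[dspec.informative_map[l]]
            params.append(_informative_params(src, pi, dspec, sub_seed))
        else:
            params.append(_noninformative_params(
                spec, pi, target_means,
                variant=3 + domain_index * 7 + l, seed=sub_seed))
    blocks, labels = [], []
    for l, g in enumerate(params):
        blocks.append(sample_subgroup(dspec.n_per_subgroup, g.mu, g.theta, rng))
        labels.append(np.full(dspec.n_per_subgroup, l))
    data = SampleMatrix(values=np.vstack(blocks),
                        domain_id=f"aux{domain_index + 1}")
    return data, params, np.concatenate(labels)


def generate_example1(card_A: int, spec: NetworkSpec, n0: int, seed: int
                      ) -> Tuple[SampleMatrix, Dict[int, SampleMatrix],
                                 SimTruth]:
    """Overall-similarity design: K = 5 auxiliary domains, L = 3 each.

    The first ``card_A`` domains are informative: their subgroup ``l`` is
    a perturbation of target subgroup ``l``.  The remaining domains are
    unrelated.  Every auxiliary subgroup has ``3 * n0`` samples.
    """
    K = 5
    if not 0 <= card_A <= K:
        raise ValueError(f"card_A must lie in [0, {K}]")
    rng = np.random.default_rng(seed)
    target, target_params, target_labels = generate_target(
        spec, n0, seed=int(rng.integers(0, 2 ** 31 - 1)))
    aux_data: Dict[int, SampleMatrix] = {}
    aux_params: Dict[int, List[SubgroupParams]] = {}
    memberships: Dict[str, np.ndarray] = {"target": target_labels}
    for k in range(K):
        informative = {l: l for l in range(3)} if k < card_A else {}
        dspec = DomainSpec(n_per_subgroup=3 * n0, L=3,
                           informative_map=informative)
        data, params, labels = _generate_domain(
            spec, dspec, target_params, k,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        aux_data[k] = data
        aux_params[k] = params
        memberships[data.domain_id] = labels
    informative_sets = {
        l: {(k, l) for k in range(card_A)} for l in range(3)
    }
    truth = SimTruth(target_params=target_params, aux_params=aux_params,
                     memberships=memberships,
                     informative_sets=informative_sets)
    return target, aux_data, truth


def generate_example2(spec: NetworkSpec, n0: int, seed: int
                      ) -> Tuple[SampleMatrix, Dict[int, SampleMatrix],
                                 SimTruth]:
    """Local-similarity design: K = 6 domains, subgroup counts (2,3,4,3,3,3).

    For k = 1, 2, 3 only the k-th subgroup of the k-th domain is
    informative, matching the k-th target subgroup; every other auxiliary
    subgroup is unrelated.  Auxiliary subgroup size is ``3 * n0``.
    """
    counts = (2, 3, 4, 3, 3, 3)
    rng = np.random.default_rng(seed)
    target, target_params, target_labels = generate_target(
        spec, n0, seed=int(rng.integers(0, 2 ** 31 - 1)))
    aux_data: Dict[int, SampleMatrix] = {}
    aux_params: Dict[int, List[SubgroupParams]] = {}
    memberships: Dict[str, np.ndarray] = {"target": target_labels}
    for k, L_k in enumerate(counts):
        informative = {k: k} if k < 3 else {}
        dspec = DomainSpec(n_per_subgroup=3 * n0, L=L_k,
                           informative_map=informative)
        data, params, labels = _generate_domain(
            spec, dspec, target_params, k,
            seed=int(rng.integers(0, 2 ** 31 - 1)))
        aux_data[k] = data
        aux_params[k] = params
        memberships[data.domain_id] = labels
    informative_sets = {l: ({(l, l)} if l < 3 else set()) for l in range(3)}
    truth = SimTruth(target_params=target_params, aux_params=aux_params,
                     memberships=memberships,
                     informative_sets=informative_sets)
    return target, aux_data, truth
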