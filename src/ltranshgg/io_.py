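"""Readers, writers, preprocessing, network export and pipeline driver."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from . import __version__
from .core import SampleMatrix
from .metrics import (MetricsReport, clustering_error, match_subgroups,
                      mse_params, support_rates)
from .mixture import EMConfig, GGMMResults, GraphicalGaussianMixture
from .transfer import (LocalTransfer, TransferConfig, TransferResult)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "NetworkExport",
    "read_expression",
    "write_expression",
    "preprocess",
    "export_networks",
    "run_pipeline",
]

_ZERO_TOL = 1e-8


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Mirrors the CLI flags; unknown subgroup numbers are estimated via
    the fusion solution path unless ``fixed_L`` is set.
    """

    target_path: str
    aux_paths: List[str] = field(default_factory=list)
    out_dir: str = "ltranshgg_out"
    transpose: bool = False
    log10_1p: bool = False
    sd_threshold: float = 0.0
    c: float = 5.0
    L_max: int = 6
    fixed_L: Optional[int] = None
    lambda_sparsity: Optional[float] = None
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.sd_threshold < 0:
            raise ValueError("sd_threshold must be >= 0")
        if self.c <= 0:
            raise ValueError("c must be positive")
        paths = [self.target_path] + list(self.aux_paths)
        if len(set(paths)) != len(paths):
            raise ValueError("input paths must be distinct")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".csv",):
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix in (".mtx",):
        return "mtx"
    raise ValueError(f"cannot infer format from {path.name!r}; pass fmt=")


def read_expression(path, fmt: Optional[str] = None,
                    transpose: bool = False,
                    domain_id: str = "target",
                    drop_missing: bool = True) -> SampleMatrix:
    """Read a sample-by-feature matrix from CSV/TSV or MatrixMarket.

    CSV/TSV files carry feature names in the header row; a leading
    non-numeric column is treated as sample identifiers.  MatrixMarket
    files may have sidecar ``<stem>_rows.txt`` / ``<stem>_cols.txt``
    name files.  ``transpose=True`` swaps the roles of rows and columns
    after reading.  Features containing missing values are dropped at
    ingestion (``drop_missing``, logged), since downstream containers
    require complete data.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    feature_names = None
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep)
        except Exception as exc:
            raise ValueError(f"failed to parse {path}: {exc}") from exc
        if df.shape[1] and df.iloc[:, 0].dtype == object:
            df = df.set_index(df.columns[0])
        # unparseable strings are errors; genuinely missing cells are not
        def bad_cells(col):
            return pd.to_numeric(col, errors="coerce").isna() & col.notna()

        bad = df.columns[df.apply(lambda c: bad_cells(c).any())]
        if len(bad):
            line = int(np.argmax(bad_cells(df[bad[0]]).to_numpy())) + 2
            raise ValueError(f"{path}: non-numeric cell in column "
                             f"{bad[0]!r} near line {line}")
        values = df.apply(pd.to_numeric, errors="coerce").to_numpy(
            dtype=float)
        feature_names = list(df.columns)
    else:
        values = np.asarray(mmread(str(path)).todense() if hasattr(
            mmread(str(path)), "todense") else mmread(str(path)), dtype=float)
        stem = path.with_suffix("")
        cols = Path(f"{stem}_cols.txt")
        if cols.exists():
            feature_names = cols.read_text().split()
    if transpose:
        values = values.T
        feature_names = None
    if drop_missing and np.isnan(values).any():
        keep = ~np.isnan(values).any(axis=0)
        if feature_names is not None:
            gone = [n for n, k in zip(feature_names, keep) if not k]
            logger.info("dropping %d feature(s) with missing values: %s",
                        len(gone), ", ".join(gone[:20]))
            feature_names = [n for n, k in zip(feature_names, keep) if k]
        values = values[:, keep]
    return SampleMatrix(values=values, domain_id=domain_id,
                        feature_names=feature_names)


def write_expression(data: SampleMatrix, path, fmt: Optional[str] = None
                     ) -> None:
    """Write a sample matrix to CSV/TSV or MatrixMarket."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    names = data.feature_names or [f"f{j}" for j in range(data.p)]
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(data.values, columns=names).to_csv(path, sep=sep,
                                                        index=False)
    else:
        mmwrite(str(path), coo_matrix(data.values))
        Path(f"{path.with_suffix('')}_cols.txt").write_text(
            "\n".join(names) + "\n")


def preprocess(data: SampleMatrix, log10_1p: bool = False,
               sd_threshold: float = 0.1,
               return_dropped: bool = False):
    """Optional log10(1+x) transform and low-variability feature filter.

    Features with any missing value or post-transform standard
    deviation below ``sd_threshold`` are dropped; dropped names are
    logged.  Idempotent when the log transform is off.
    """
    values = data.values
    if log10_1p:
        if np.any(values < 0):
            raise ValueError("negative values are incompatible with the "
                             "log10(1+x) transform")
        values = np.log10(1.0 + values)
    sds = values.std(axis=0, ddof=1)
    keep = sds >= sd_threshold
    names = data.feature_names or [f"f{j}" for j in range(data.p)]
    dropped = [names[j] for j in range(data.p) if not keep[j]]
    if dropped:
        logger.info("dropping %d low-variability feature(s): %s",
                    len(dropped), ", ".join(dropped[:20]))
    out = SampleMatrix(values=values[:, keep], domain_id=data.domain_id,
                       feature_names=[n for n, k in zip(names, keep) if k]
                       if data.feature_names is not None else None)
    if return_dropped:
        return out, dropped
    return out


@dataclass
class NetworkExport:
    """Edge list and degree table of one subgroup network."""

    subgroup: int
    edges: List[Tuple[str, str, float]]
    degrees: Dict[str, int]


def network_export(theta: np.ndarray, names: Sequence[str],
                   subgroup: int) -> NetworkExport:
    p = theta.shape[0]
    edges = []
    degrees = {str(n): 0 for n in names}
    for i in range(p):
        for j in range(i + 1, p):
            if abs(theta[i, j]) > _ZERO_TOL:
                edges.append((str(names[i]), str(names[j]),
                              float(theta[i, j])))
                degrees[str(names[i])] += 1
                degrees[str(names[j])] += 1
    return NetworkExport(subgroup=subgroup, edges=edges, degrees=degrees)


def export_networks(results: Sequence[TransferResult],
                    names: Optional[Sequence[str]], out_dir) -> List[Path]:
    """Write per-subgroup TSV edge lists and a degree-ranked node table."""
    if not results:
        raise ValueError("no transfer results to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = results[0].theta_hat.shape[0]
    names = list(names) if names is not None else [f"f{j}" for j in range(p)]
    written = []
    for r in results:
        exp = network_export(r.theta_hat, names, r.target_subgroup)
        edge_path = out_dir / f"subgroup{r.target_subgroup}_edges.tsv"
        with edge_path.open("w") as fh:
            fh.write("node_i\tnode_j\tweight\n")
            for a, b, w in exp.edges:
                fh.write(f"{a}\t{b}\t{w:.10g}\n")
        deg_path = out_dir / f"subgroup{r.target_subgroup}_degrees.tsv"
        ranked = sorted(exp.degrees.items(), key=lambda kv: (-kv[1], kv[0]))
        with deg_path.open("w") as fh:
            fh.write("node\tdegree\n")
            for node, deg in ranked:
                fh.write(f"{node}\t{deg}\n")
        written += [edge_path, deg_path]
    return written


def _mat_to_list(m: Optional[np.ndarray]):
    return None if m is None else np.asarray(m).tolist()


def fit_to_dict(fit: GGMMResults) -> dict:
    return {
        "domain_id": fit.data.domain_id,
        "L_hat": fit.L_hat,
        "proportions": fit.proportions.tolist(),
        "means": [m.tolist() for m in fit.means],
        "precisions": [t.tolist() for t in fit.precisions],
        "pseudo_sizes": fit.pseudo_sizes.tolist(),
        "labels": fit.labels.tolist(),
        "lambda_used": fit.lambda_used,
        "loglik": fit.loglik,
        "converged": fit.converged,
    }


def transfer_to_dict(r: TransferResult) -> dict:
    return {
        "target_subgroup": r.target_subgroup,
        "transferred": r.transferred,
        "theta_hat": _mat_to_list(r.theta_hat),
        "delta_hat": _mat_to_list(r.delta_hat),
        "lambda1": r.lambda1,
        "lambda2": r.lambda2,
        "bic_trace": r.bic_trace,
        "informative_set": {
            "members": [list(m) for m in r.informative_set.members],
            "threshold": r.informative_set.threshold,
            "s_hat": r.informative_set.s_hat,
            "n_0l": r.informative_set.n_0l,
        } if r.informative_set is not None else None,
        "weights": ({f"{k},{lp}": v
                     for (k, lp), v in r.weights.alphas.items()}
                    if r.weights is not None else None),
    }


def evaluate_fit(labels_est: np.ndarray, labels_true: np.ndarray,
                 est_means: Sequence[np.ndarray],
                 est_precisions: Sequence[np.ndarray],
                 true_means: Sequence[np.ndarray],
                 true_precisions: Sequence[np.ndarray]) -> MetricsReport:
    """Bundle the per-fit metrics into one report."""
    matching = match_subgroups(labels_est, labels_true)
    mse_mu, mse_theta = mse_params(est_means, est_precisions, true_means,
                                   true_precisions, matching)
    tpr, fpr = support_rates(est_precisions, true_precisions, matching)
    return MetricsReport(
        L_hat=len(est_means),
        CE=clustering_error(labels_est, labels_true),
        mse_mean=mse_mu, mse_precision=mse_theta, tpr=tpr, fpr=fpr)


def run_pipeline(config: RunConfig) -> Path:
    """Initialization + transfer on files named in ``config``.

    Writes fits JSON, transfer JSON, per-subgroup networks, a
    reproducibility manifest (seed, config hash, version) and a log to
    ``config.out_dir``; returns that directory.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("ltranshgg")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    try:
        target = read_expression(config.target_path,
                                 transpose=config.transpose,
                                 domain_id="target")
        target = preprocess(target, log10_1p=config.log10_1p,
                            sd_threshold=config.sd_threshold)
        kept = target.feature_names
        aux: Dict[int, SampleMatrix] = {}
        for k, path in enumerate(config.aux_paths):
            d = read_expression(path, transpose=config.transpose,
                                domain_id=f"aux{k + 1}")
            d = preprocess(d, log10_1p=config.log10_1p,
                           sd_threshold=0.0)
            if kept is not None and d.feature_names is not None:
                idx = [d.feature_names.index(nm) for nm in kept]
                d = SampleMatrix(values=d.values[:, idx],
                                 domain_id=d.domain_id, feature_names=kept)
            if d.p != target.p:
                raise ValueError(f"auxiliary domain {k + 1} has p={d.p}, "
                                 f"target has p={target.p}")
            aux[k] = d
        em_cfg = EMConfig(L_max=config.L_max, fixed_L=config.fixed_L,
                          lambda_sparsity=config.lambda_sparsity,
                          seed=config.seed)
        logger.info("fitting target domain (n=%d, p=%d)", target.n, target.p)
        target_fit = GraphicalGaussianMixture(target, em_cfg).fit_select()
        aux_fits: Dict[int, GGMMResults] = {}
        for k, d in aux.items():
            logger.info("fitting auxiliary domain %d (n=%d)", k + 1, d.n)
            aux_fits[k] = GraphicalGaussianMixture(d, em_cfg).fit_select()
        model = LocalTransfer(target_fit, aux_fits, aux,
                              TransferConfig(c=config.c))
        transfer_res = model.fit()
        fits = {"target": fit_to_dict(target_fit)}
        for k, f in aux_fits.items():
            fits[f"aux{k + 1}"] = fit_to_dict(f)
        (out_dir / "fits.json").write_text(
            json.dumps(fits, sort_keys=True, indent=1))
        (out_dir / "transfer.json").write_text(json.dumps(
            [transfer_to_dict(r) for r in transfer_res.results],
            sort_keys=True, indent=1))
        export_networks(transfer_res.results, kept, out_dir / "networks")
        cfg_dict = asdict(config)
        manifest = {
            "seed": config.seed,
            "config": cfg_dict,
            "config_hash": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
            "version": __version__,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1))
        logger.info("pipeline finished: %s", out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out_dir
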