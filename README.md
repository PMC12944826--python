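# ltranshgg

Subgroup-local transfer learning for Gaussian graphical model (GGM)
heterogeneity analysis.

Heterogeneous biological samples — cancer cohorts, single-cell
populations — are often modeled as a **Gaussian graphical mixture**: a
finite mixture of multivariate normals in which each latent subgroup
*l* has its own mean vector μ<sub>l</sub> and sparse precision matrix
Θ<sub>l</sub>, whose nonzero off-diagonals are the edges of the
subgroup's conditional-dependence network. When a biologically
important subgroup is rare, its network estimate is unstable. This
package borrows strength from auxiliary data sets (other cohorts,
stages, batches) **subgroup by subgroup**, without assuming the domains
share a subgroup count or overall structure, and with a hard safeguard
against negative transfer from unrelated sources.

It is aimed at statisticians and computational biologists estimating
subgroup-specific gene networks (e.g. from scRNA-seq expression
matrices) when some subgroups have few samples.

## Method

Three stages, for a target domain with n samples and K auxiliary
domains over the same p features:

1. **Initialization.** A penalized EM fits a sparse Gaussian graphical
   mixture to every domain separately. The M-step updates each
   precision via a weighted graphical lasso; a concave (MCP) fusion
   penalty on pairwise differences of stacked subgroup parameters
   merges similar components along a solution path, so the subgroup
   number L̂ is estimated (BIC over the path) rather than fixed. Each
   auxiliary subgroup (k, l′) yields a responsibility-weighted pseudo
   covariance Σ̃<sub>l′</sub><sup>(k)</sup> and pseudo sample size
   n<sub>kl′</sub>.
2. **Prescreening and adaptive weighting.** For each target subgroup
   l, the divergence Δ̂<sub>ll′</sub><sup>(k)</sup> =
   Θ̂<sub>l</sub><sup>(0)</sup> Σ̃<sub>l′</sub><sup>(k)</sup> − I is
   measured by the symmetrized max-column-ℓ1 norm and compared against
   the single-domain estimation-error order
   c·ŝ·√(log p / n<sub>0l</sub>) (c = 5, ŝ the maximum column
   support size of Θ̂<sub>l</sub><sup>(0)</sup>). Retained sources are
   averaged with weights α<sub>kl′</sub> ∝ n<sub>kl′</sub> /
   ‖Δ̂<sub>ll′</sub><sup>(k)</sup>‖<sub>1,∞</sub>. **An empty set stops
   transfer for that subgroup**: the initial estimate is returned
   unchanged.
3. **Local transfer.** The aggregate divergence is soft-thresholded at
   λ₁ = 2‖Θ̂<sub>l</sub><sup>(0)</sup>‖<sub>1,∞</sub>√(log p / n), and
   the final precision solves a columnwise ℓ1-penalized quadratic
   program driven by the aggregated covariance, with λ₂ tuned by a
   BIC-type criterion.

See `docs/methods.md` for the estimators in full, numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Worked example

Simulate a local-similarity benchmark — six auxiliary domains with
subgroup counts (2, 3, 4, 3, 3, 3), where only the k-th subgroup of the
k-th domain (k = 1, 2, 3) matches a target subgroup — then fit and
transfer:

```python
from ltranshgg import (GraphicalGaussianMixture, LocalTransfer, EMConfig,
                       NetworkSpec, generate_example2)

spec = NetworkSpec(kind="tridiagonal", p=30, seed=0)
target, aux, truth = generate_example2(spec, n0=100, seed=7)

em = EMConfig(fixed_L=3, seed=7)                 # oracle subgroup number
target_fit = GraphicalGaussianMixture(target, em).fit()
print(target_fit.summary())

aux_fits = {k: GraphicalGaussianMixture(d, em).fit() for k, d in aux.items()}
res = LocalTransfer(target_fit, aux_fits, aux).fit()
print(res.summary())
```

```
Gaussian graphical mixture fit
==============================================
domain: target   n = 300   p = 30
subgroups (L_hat): 3   converged: True (1 iterations)
log-likelihood: -13489.483   BIC: 28370.688
----------------------------------------------
subgroup       pi   n_pseudo   edges
       0   0.3600      103.1      24
       1   0.3700      109.9      27
       2   0.2700       87.0      11

Local transfer results
==========================================================
target domain: n = 300, p = 30, L_hat = 3
----------------------------------------------------------
subgroup  transferred  sources   lambda1   lambda2   edges
       0         True        2    0.4537    0.1065      46
       1         True        3    0.4670    0.0836      36
       2         True        2    0.5000    0.1065      47
```

Each target subgroup found its informative auxiliary source and
transferred: on this draw the dominant aggregation weight (0.92, 0.73
and 0.96) lands on the one truly informative auxiliary subgroup, and
the squared Frobenius error of the three precision estimates drops from
(2.70, 3.86, 5.08) to (1.10, 2.28, 1.32) relative to the simulation
truth. Rerunning with no informative domains (`generate_example1`
with `card_A=0`) leaves every `transferred` flag False and the
initialization estimates untouched — the negative-transfer safeguard.

## Command line

```
ltranshgg simulate --example 2 --network tridiagonal --p 30 --n0 100 --seed 7 --out sim/
ltranshgg transfer --target sim/target.csv --aux sim/aux1.csv --aux sim/aux2.csv --out run/
ltranshgg evaluate --truth sim/truth.json --fit run/fits.json --out metrics.csv
ltranshgg run --config config.yaml        # YAML mirroring the flags
```

Expression matrices are CSV/TSV (samples as rows, `--transpose` to
flip) or MatrixMarket with sidecar name files; raw TPM tables can be
preprocessed with `--log10-1p` and the default SD ≥ 0.1 feature filter.
Outputs are JSON fits, per-subgroup TSV edge lists and degree tables,
and a reproducibility manifest.

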