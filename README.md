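# multida

Sparse multiblock discriminant analysis for integrative genomic data.

Complex diseases leave traces in several data modalities at once —
genotype (SNP), copy number (CNV), DNA methylation (DM) and gene
expression (GE) — measured on the same individuals.  `multida` couples
such *multiblock* data with a binary case/control label in one sparse
latent-variable model, so that the features it selects are jointly
informative across modalities **and** discriminative for the phenotype.
It is aimed at computational biologists benchmarking multi-omics
feature-selection methods or applying them to case/control cohorts.

## The model

Each block `X_j` (samples × features, zero-mean columns) is summarized
by a one-dimensional latent variable `v_j = χ_j α_j` with a sparse
loading vector `α_j`.  The loadings maximize the weighted sum of squared
covariances between the latent variables of linked blocks,

    maximize  Σ_{j≠k}  d_jk (α_j' χ_j' χ_k α_k)²
    subject to ‖χ_j α_j‖² = N  and an elastic-net penalty on each α_j,

where the binary design matrix `C` declares which block pairs are linked
(`SNP, CNV, DM → GE → class` in the default genomic graph) and the
weight matrix `D` rebalances the pairs (the GE–class pair is weighted
3×, so the discriminant coupling is not swamped by the larger blocks).
`χ_j = X_j` for every feature block; the class block is augmented with
discriminative least-squares slack variables,

    χ_class = X_class + b ⊙ m ,   m ≥ 0,

where `b` is the ±1 class direction — the slack can push a working label
away from the decision boundary but never across it, enlarging the
between-class margin of the expression–class regression.

Optimization is cyclic (Wold's procedure): each block's loading is
refreshed from its *inner component* `υ_j = Σ_k d_jk (v_j'v_k) v_k` by a
univariate soft-threshold (UST) update `α_j(i) = sign(g_i)(|g_i|−λ_j)₊`
with `g = χ_j'υ_j`, then renormalized.  The shrinkage level `λ_j` is a
per-block fraction of the largest gradient magnitude, chosen by K-fold
cross-validation; features whose loadings survive the thresholding in
any extracted rank are the selected features.  Setting `sgcca_mode`
replaces `D` by `C` and removes the slack, which reduces the model to
sparse generalized canonical correlation analysis (SGCCA) — the
built-in ablation baseline.

## Worked example

```python
import multida as mda

data, truth = mda.simulate_dataset(mda.SimConfig(n=300), seed=1)
graph = mda.default_genomic_graph()
result = mda.fit(data, graph, mda.FitOptions(seed=1))
selected = mda.score_selection(mda.select_features(result), truth)
```

Running `python examples/simulate_and_fit.py` (which does exactly this
and prints diagnostics) gives

```
extracted 2 rank(s)
  rank 1: 24 sweeps, objective 3.848e+05 -> 4.211e+05 (converged)
  rank 2: 6 sweeps, objective 1.064e+05 -> 1.067e+05 (converged)
  SNP: selected 16 features, 9/10 true
  CNV: selected 12 features, 7/10 true
  DM: selected 39 features, 9/10 true
  GE: selected 9 features, 8/10 true
pooled over blocks: TPR 0.825  PPV 0.434  ACCU 0.923
```

The objective trace is non-decreasing within each rank (the Wold
guarantee); each block's sparse loading concentrates on its ten planted
signal features; TPR/PPV/ACCU score the pooled selection against the
generator's ground truth.  At the full study size (N = 500, 50
replications) recovery is substantially better — see below.

Other entry points: `examples/replication_study.py` (benchmark of both
fitting modes), `examples/custom_blocks.py` (your own matrices and a
custom block graph), and a thin CLI:

```sh
multida simulate --n 500 --seed 7 --out simdata
multida fit --blocks simdata/block_SNP.csv ... --labels simdata/labels.csv --scale
multida evaluate --fit-dir fit_out --truth simdata/truth.json
multida study --reps 50 --seed 7
```

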