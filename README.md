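# sparsegmm

Bayesian clustering of high-dimensional data under a sparse Gaussian
mixture model, with the number of clusters inferred rather than
specified.

## The problem

In many genomics settings — bulk expression panels, single-cell RNA-seq —
the number of features p (genes) far exceeds the number of observations
n (samples, cells), and only a small panel of features actually
separates the subpopulations.  Classical mixture modeling breaks down
in this regime, and most practical tools require the number of clusters
K as an input.  `sparsegmm` is for analysts who want model-based
clustering of a p × n matrix (p ≫ n allowed) that (i) selects the
discriminating features and (ii) estimates K, within one coherent
posterior.

## The model

Observations follow a Gaussian mixture written as a signal-plus-noise
matrix model,

    Y_i = μ_{z_i} + ε_i,   ε_i ~ N_p(0, I_p),   E(Y) = μLᵀ,

where the p × K center matrix μ is **jointly s-sparse**: at most s rows
are nonzero and all clusters share that support.  Row sparsity is
induced by a joint spike-and-slab LASSO prior — each feature row is
gated by an indicator ξ_j between a concentrated Laplace spike
ψ(·|λ₀) and a diffuse Laplace slab ψ(·|λ₁), with inclusion probability
θ ~ Beta(1, p^{1+κ} log p) — while labels get Categorical(w) with
w ~ Dirichlet_K(α) and K itself a truncated Poisson on {1, …, K_max}.
Inference is by a trans-dimensional Gibbs sampler whose birth/death
moves create and remove empty mixture components; partitions are
estimated by the label-aligned posterior mode of z.  A constrained
maximum-likelihood counterpart (minimize ‖Y − μLᵀ‖²_F over jointly
s-sparse μ), the ARI/NMI/minimum-Hamming clustering metrics, the
benchmark scenario generators, and an scRNA-seq preprocessing recipe
are included.  See `docs/methods.md` for the full account.

## Worked example

Simulate a benchmark data set (p = 400 genes, n = 200 observations,
K* = 3 clusters separated on the first 12 features), fit, and evaluate:

```sh
$ sparsegmm simulate --scenario 1 --K 3 --s 12 --seed 7 --out-dir data
wrote Y (400x200), z_true, mu_true to data

$ sparsegmm fit data/Y.csv --out-dir run --seed 7
K_hat = 3; outputs in run

$ sparsegmm eval data/z_true.txt run/z_hat.txt
ARI: 0.952699
NMI: 0.934023
Hamming mis-clustering: 0.015000
```

The sampler starts from 2 k-means clusters and grows to the correct
K̂ = 3 through accepted birth moves (61 in this run, per
`run/report.json`).  The estimated partition misplaces 3 of the 200
observations (Hamming rate 0.015), giving an adjusted Rand index of
0.95.  Feature selection is read off the posterior inclusion
probabilities in `run/xi_mean.txt`: here exactly features 1–12 have
posterior inclusion above 0.5 (the true support), and no other feature
exceeds 0.023.

The same works from Python:

```python
from sparsegmm import Hyperparams, McmcConfig, ari, fit, scenario1

Y, z_true, mu_true = scenario1(3, 12, seed=7)
res = fit(Y, Hyperparams(), McmcConfig(n_iter=2500, burn_in=500, seed=7))
print(res.K_hat, ari(z_true, res.z_hat))
```

For real scRNA-seq counts, `sparsegmm preprocess counts.csv --out Y.csv`
applies the standard recipe (drop genes with total count ≤ 10,
log2(y+1), per-cell normalization, per-gene standardization) before
fitting; MTX input and a `--transpose` flag for cells × genes files are
supported.

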