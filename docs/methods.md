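# Methods

## Model

`sparsegmm` clusters a p × n data matrix Y (features × observations,
typically p ≫ n) under the signal-plus-noise mixture

    Y_i = μ_{z_i} + ε_i,    ε_i ~ N_p(0, I_p),   i = 1, …, n,

where μ = (μ_1, …, μ_K) ∈ R^{p×K} holds the cluster centers and
z ∈ {1..K}^n the memberships, so E(Y) = μLᵀ with L the one-hot
membership matrix.  Two structural ideas carry the method into high
dimensions:

* **Joint sparsity.**  At most s rows of μ are nonzero and all clusters
  share the same support.  Only a small panel of features separates the
  clusters; everything else is noise.
* **Unknown K.**  The number of clusters is a parameter with a prior,
  not an input.

The identity working covariance is deliberate, even when the data are
generated with heteroscedastic or heavy-tailed noise: the target of
inference is the mean matrix μLᵀ, and the posterior for μLᵀ remains
well behaved whenever the true noise covariance has bounded spectrum.
The package never estimates Σ; the true covariance enters only the
simulation module.

## Prior

For each feature row j, a shared binary indicator ξ_j gates the whole
row of μ between two Laplace distributions ψ(x|λ) = (λ/2)e^{−λ|x|}
(a joint spike-and-slab LASSO):

    π(μ_{1j}, …, μ_{Kj} | ξ_j) = Π_k ψ(μ_{kj} | λ_1)^{ξ_j} ψ(μ_{kj} | λ_0)^{1−ξ_j},
    ξ_j | θ ~ Bernoulli(θ),      θ ~ Beta(1, β_θ),

with spike rate λ_0 ≫ slab rate λ_1.  The remaining structure is

    z_i | w ~ Categorical(w),    w | K ~ Dirichlet_K(α),
    π(K) ∝ e^{−λ} λ^K / K!,      K ∈ {1, …, K_max}.

A column-wise (non-joint) spike-and-slab variant, in which each column
of μ carries its own support, is a straightforward relaxation of the
same machinery; the package keeps the joint prior as the default and
only interface because shared support is what the clustering geometry
rewards (the column-wise variant changes the attainable sparsity rate,
not the sampler structure).

### Default hyperparameters

| parameter | default | meaning / rationale |
|---|---|---|
| λ_0 | 100 | spike rate; keeps off-support center entries within ~0.01–0.03 of zero |
| λ_1 | 1 | slab rate; weakly shrinks genuine signal entries |
| κ | 0.1 | exponent in β_θ = p^{1+κ} log p |
| β_θ | p^{1+κ} log p | pushes the prior inclusion probability toward 0 at a super-linear rate in p, which is what makes support recovery consistent; override for small-p experiments (for p = 1 the value is floored at 1 to keep the Beta proper) |
| α | 1 | symmetric Dirichlet shape (uniform on the simplex); theory wants α ≥ 1 |
| λ (Poisson) | 2 | truncated Poisson rate on K; mild preference for few clusters |
| K_max | 20 | conservative cap on K |

## Posterior computation

One sweep of the sampler updates, in order: w (conjugate Dirichlet),
z (independent categorical draws, log-space normalized), μ (exact
entrywise draws), (ξ, θ) (Bernoulli with log-odds formed from the two
Laplace log-densities, then conjugate Beta), and finally the
trans-dimensional moves on K.

**Center updates.**  Conditional on labels, each entry of an occupied
column has density ∝ exp(−n_k(μ − m)²/2 − λ|μ|) with m the cluster mean
of that coordinate.  This is a two-piece normal: a two-component mixture
of truncated normals on (−∞,0] and [0,∞) with means m ± λ/n_k and
variance 1/n_k.  The mixture weight and the truncated draws are both
computed through log-CDFs (`log_ndtr` / `ndtri_exp`), so the spike rate
λ_0 = 100 can push a branch 50+ standard deviations into the tail
without loss of accuracy.  Empty columns are refreshed from the prior.

**Birth/death moves on K.**  Each sweep makes (by default) two
Metropolis–Hastings attempts, each choosing birth or death with
probability ½.  A birth proposes K → K+1 by drawing a new center column
from the current-ξ spike-and-slab prior (that draw cancels against the
prior in the ratio), carving a weight b ~ Beta(α, n + Kα) out of the
existing weights, and inserting the empty component at a uniformly
random position.  With this proposal every b-dependent term — Dirichlet
density, categorical likelihood (1−b)^n, Jacobian (1−b)^{K−1}, and
proposal density — cancels exactly, leaving

    log r = log π(K+1) − log π(K)
          + log Γ((K+1)α) − log Γ(Kα)
          + log Γ(n + Kα) − log Γ(n + (K+1)α)
          + log(K+1) − log(E+1),

with E the number of currently empty components.  A death removes a
uniformly chosen *empty* component with the inverse ratio.  Occupied
components are never killed or split: clusters are created empty, are
immediately exposed to the label update (a newborn component with a
small weight still captures badly-fit observations, whose likelihood
advantage is exponential in their misfit), and disappear only after the
label updates have vacated them.  This "empty-component allocation
sampler" design trades some trans-dimensional mobility for easily
verified correctness; at the problem sizes the package targets the
label updates vacate and populate components fast enough that K mixes
within a few hundred sweeps.

**Initialization.**  Labels from K-means with K = round(λ) clusters
(default 2), centers at the cluster means, ξ = 0, θ at its prior mean.
Growth to the true K happens through the birth moves.

**Validation.**  Because the sampler is derived here rather than copied
from a reference, its correctness is established by simulation
consistency, which this package treats as the primary gate:

* a joint-distribution ("getting it right") test compares marginal
  draws of (θ, Σξ, K, ‖μ‖_F) from i.i.d. prior simulation against a
  successive-conditional chain that alternates data resampling with one
  Gibbs sweep (two-sample KS and χ² tests at α = 0.01);
* a prior-only chain (n = 0) must leave the prior invariant: the
  K-marginal is checked against the truncated Poisson pmf and the
  θ-marginal against Beta(1, β_θ) over 20 000 sweeps.

These tests exercise every full conditional and the birth/death
acceptance ratio; a deliberately mis-scaled prior ratio shifts the
chain's K-marginal and drives the χ² statistic toward rejection, while
gross conditional errors fail the tests outright.

## Point estimation

Mixture posteriors are invariant under relabeling, so raw averages of
labels or centers are meaningless.  Every stored label vector is aligned
to a pivot — the kept sample with the highest log joint density — by
maximum-agreement assignment (Hungarian algorithm on the K × K
confusion matrix, padded when sample and pivot disagree on K).  The
partition estimate takes the per-observation modal aligned label (ties
to the smallest label); K̂ is the number of distinct labels the mode
actually uses.  Center estimates average the aligned μ columns
entrywise.  This is one consistent reading of "posterior mode of the
z_i"; it is deterministic and costs O(K³) per sample.

## Constrained MLE

The frequentist counterpart minimizes ‖Y − μLᵀ‖²_F over jointly
s-sparse μ and valid allocations — minimax-optimal but combinatorial.
For fixed labels the optimal sparse centers have a closed form: take
cluster means, score each row by its exact SSE reduction Σ_k n_k μ̂²_kj,
keep the top s rows (ties to the smaller index), zero the rest.  The
package ships (a) an exhaustive solver over canonical labelings
(restricted-growth strings, guarded to K^n ≤ 10⁶) as a certified
oracle, and (b) a Lloyd-style alternating heuristic with seeded
restarts, empty-cluster reseeding at worst-fit points, and a
first-improvement single-label refinement that leaves the returned
labeling 1-opt.  On tiny instances the heuristic reproduces the
exhaustive optimum; at scale it inherits the usual local-optimum
caveats of k-means-type methods.

## Metrics

ARI and NMI are computed from the contingency table; NMI normalizes
mutual information by the arithmetic mean of the two partition
entropies by default (the geometric mean is available via a flag — the
two coincide at the extremes and differ little in practice; the
arithmetic choice matches the most common reference implementation
default).  When one partition has a single cluster its entropy is zero:
NMI returns 1 if the partitions are identical and raises otherwise.
The minimum Hamming mis-clustering rate d_H minimizes the mismatch
fraction over label permutations via the same maximum-agreement
assignment used for trace alignment, padded when the cluster counts
differ; tests verify it against brute-force enumeration over all
permutations on small instances.

## Synthetic data

The three scenario generators emulate a standard benchmark design
(p = 400, n = 200, support = the first s coordinates):

* **Scenario I** (K* ∈ {3, 5}, s ∈ {6, 12}): identity covariance;
  centers 3·1, −1.5·1, 0 with weights (0.3, 0.3, 0.4) for K* = 3, and
  4·1, −4·1, 0, 4·(−1,1,…), 1.5·(1,−1,…) with uniform weights for
  K* = 5.
* **Scenario II** (K* = 3, s = 8): centers (5,2,…), (10,5,…), (15,2,…)
  on the support, weights (0.02, 0.48, 0.5) — a four-point cluster in
  expectation — and cluster 2's variance inflated to 4 on the support.
* **Scenario III**: Scenario II's centers and diagonal covariances, but
  multivariate-t noise with ν = 5 degrees of freedom and weights
  (0.2, 0.4, 0.4).  The diagonals are read as the *covariance* of the t
  noise: the generator draws Gaussian noise with scale (ν−2)/ν · Σ and
  divides by √(g/ν), g ~ χ²_ν, so the resulting t noise has covariance
  exactly Σ.  (Reading Σ as the t scale matrix instead — which inflates
  the actual covariance by ν/(ν−2) = 5/3 — is available via
  ``t_matrix="scale"``; under that heavier-noise reading the benchmark
  clustering accuracy drops visibly below the reference level, which is
  what settled the default.)

What the generators deliberately do not emulate: correlated noise,
non-diagonal covariances, scattered (non-prefix) supports, cluster-
specific supports, and any of the messiness of real scRNA-seq data
(dropout, library-size variation, batch effects).  Passing the
benchmark suite therefore demonstrates correct inference under the
stated model and graceful degradation under heavy tails — not
performance on real single-cell data, for which the preprocessing
recipe is provided but no accuracy claim is made.

## Preprocessing recipe (scRNA-seq)

For a genes × cells count matrix: drop genes with total count ≤ 10
across cells; transform log2(y + 1); divide each cell by its total
transformed expression; standardize each gene to mean 0, variance 1
(population variance by default, sample variance via flag — the choice
is a convention and moves nothing at realistic n).  The steps are order
sensitive and applied exactly in this order.  Genes left constant after
normalization are dropped with a warning rather than producing NaNs; a
cell with no counts at all is an error, not a silent zero-division.

## Numerical choices and degenerate inputs

* All categorical/Bernoulli probabilities are formed in log space with
  max-subtraction or log-CDFs; the label draw uses Gumbel-max.
* θ is clamped to [1e−300, 1 − 1e−16] after Beta draws so boundary
  underflow cannot produce −∞ log densities.
* Zero mixture weights are admissible in the label update (log w = −∞
  simply removes the component from contention).
* Ties: row selection in the sparse-MLE projection and the modal-label
  estimate both break toward the smaller index; these choices make runs
  reproducible bit-for-bit.
* A non-finite log joint during a run aborts with the iteration number
  and state diagnostics rather than continuing silently.
* Labels are 1-based in every user-facing array and file; weights must
  sum to 1 within 1e−12.

## Problem sizes used in the shipped checks

The benchmark suite and the acceptance script run 10 replicates per
scenario setting with 500 burn-in + 2000 kept iterations (roughly 8 s
per replicate on one core).  These sizes give binomial/MC noise well
inside the tolerances checked; cluster-count recovery rates are
assessed against the reference rates through one-sided binomial bounds
at the 1% level, and mean-ARI checks carry explicit absolute
tolerances.  The Theorem-style contraction sanity checks (normalized
Frobenius risk bounded in n) run at reduced dimensions (p = 120 for the
posterior check, p = 50 for the MLE check) to keep the default test run
fast.

## Known limitations

* No split/merge moves for occupied components, and birth moves draw
  new centers from the origin-centered spike-and-slab prior.  The
  sampler therefore grows K "from below": a newborn component can only
  capture observations that fit the origin region better than their
  current cluster.  If an initialization merges two clusters whose
  centers are both far from the origin, the chain may never separate
  them (observed on heavy-tailed benchmark replicates as a K̂ one below
  the truth with a sharply lower ARI).  Initializing from more k-means
  clusters avoids this but is not the default, because under the
  misspecified identity-covariance likelihood a genuinely wide cluster,
  once split by the initializer, never re-merges — the from-below
  behavior doubles as the implicit regularization that makes the
  benchmark's heteroscedastic scenario work.  Users who suspect
  far-from-origin structure should either center/scale features first
  (the preprocessing recipe does) or raise ``McmcConfig.init_K``.
* No covariance estimation; strongly anisotropic noise that the mean
  structure cannot explain will be absorbed into extra clusters.
* The exhaustive MLE is a test oracle only; the alternating heuristic
  carries no global-optimality certificate at realistic sizes.
* Posterior summaries assume the kept samples visit the modal K
  reasonably often; if the K-trace is still drifting, extend the run.
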