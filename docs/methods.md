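# Methods

## Model

Each of N entities (genes, tumour samples, ...) carries n_r binary
variables r_ij ∈ {0,1} (transcription-factor binding calls, mutation
presence) and n_e continuous variables e_il (expression values over
samples or time points). The joint density is a finite mixture of N_m
components, each a product of independent Bernoulli terms and independent
(diagonal) Gaussians:

    p(r_i, e_i) = Σ_m α_m Π_j B(r_ij; p_mj) Π_l N(e_il; μ_ml, σ_ml)

with Σ α_m = 1. A component is read as a module: a shared binding/mutation
probability profile p_m· coupled to a shared expression pattern μ_m·.
Either block may be empty; with n_r = 0 the method reduces to
expression-only Gaussian mixture clustering.

The number of components is selected, not supplied: fitting minimizes the
penalized objective

    O(L, k) = −2 L + k λ(N)

where L is a maximized log-likelihood, k the number of free parameters and
λ(N) one of: a constant in [1, 5] (λ = 2 is the AIC), ln N (BIC),
2 ln ln N (Hannan–Quinn) or 1 + ln N (consistent AIC). Parameters are
counted as k = (N_m − 1) + N_m·n_r + 2·N_m·n_e: free mixing weights, one
Bernoulli probability per binary variable per component, and a mean plus a
standard deviation per continuous variable per component (σ is per
component *and* per variable, so both Gaussian parameters are free).

## Two likelihoods

Two versions of L appear, deliberately:

- **Inside the search**, L is the *classification* (hard-assignment)
  log-likelihood: each entity contributes ln α_z + ln f_z(x) for its
  assigned cluster z, with per-cluster maximum-likelihood parameters
  (clamped Bernoulli column means; Gaussian column means; population, 1/n,
  standard deviations) and α_m = n_m/N. This quantity decomposes over
  clusters, which is what makes incremental move evaluation possible.
- **After refinement**, the reported L is the full marginal mixture
  log-likelihood (log-sum-exp over components). The classification value
  is a lower bound on the mixture value for the same parameters, so
  refinement can only help.

## Numerical floors

Bernoulli probabilities are clamped to [1e-3, 1 − 1e-3] in estimation so
pure columns keep finite log-density. Gaussian standard deviations are
floored, default σ_floor = 0.01. The floor is not a technicality: the
classification likelihood is unbounded as a cluster's variance shrinks, so
a singleton cluster gains −ln(σ_floor) per continuous variable "for free".
The floor caps that gain, and it must be read as *the finest noise scale
the objective resolves*: a cluster whose real within-cluster σ is much
larger than the floor can be profitably shattered into degenerate
near-singleton clusters, because the per-point gain
≈ 2·n_e·ln(σ/σ_floor) then exceeds the penalty of the extra
(1 + n_r + 2·n_e) parameters. Concretely, at n_r = n_e = 20 under the AIC,
σ = 0.01 data is safe with the default floor, while σ = 0.3 data shatters
unless the floor is raised to roughly a third of the noise scale (0.1
recovers the noisy simulation design exactly; see
`examples/clear_clusters_and_network.py`). Both floors are per-run keyword
arguments through search, EM and the pipeline; parameter containers only
require σ > 0, so models generated at any noise scale remain valid
objects. Set σ_floor a little below the smallest within-cluster noise you
believe in, never orders of magnitude below it.

## Search

A Monte-Carlo simulated annealing over hard partitions. Moves, drawn with
equal probability (inapplicable kinds skipped):

- REASSIGN: one random entity to a random other cluster,
- SPLIT: a random cluster of size ≥ 2 into two random non-empty halves,
- MERGE: two random clusters,
- NEW: one random entity into a fresh singleton cluster.

Metropolis acceptance on ΔO (accept if ΔO ≤ 0, else with probability
exp(−ΔO/T)); geometric cooling T ← 0.95 T from T₀ = 10 down to 0.01, with
early stop after 20 temperature levels without improving the best-ever
objective; 50·N proposed moves per level; initial state: uniform random
assignment to max(2, N/20) clusters. All schedule fields are configurable;
the experiment drivers and acceptance script use a lighter schedule
(T₀ = 5, cooling 0.9, 20·N moves per level, early stop 8) that reaches the
same optima on the simulated designs at a fraction of the cost. Optional
restarts (default 3) run independent searches from seeds derived from the
run seed and keep the best objective; ties go to the first encountered.

Per-cluster sufficient statistics (member count, binary column sums,
continuous sums and sums of squares) give each cluster's score in
O(n_r + n_e); a move touches at most two clusters, so ΔO costs the same.
The running objective is re-synced from the per-cluster scores at every
temperature level to stop floating-point drift, and a debug audit can
rebuild the cache from scratch and compare.

All randomness flows from one named generator per run, so traces and
results are exactly reproducible from the seed. One consequence: the
search is *not* invariant to permuting entity order for a fixed seed (the
RNG stream maps to different entities); on easy instances it reaches the
same optimum, which is what the tests assert.

## EM refinement

Standard mixture EM from the search solution: E-step responsibilities
γ_im ∝ α_m f_m(x_i) computed in log space; M-step weighted updates
(α_m = Σγ/N, clamped weighted Bernoulli means, weighted Gaussian means and
floored weighted SDs) — the unique closed-form maximizers of the expected
complete-data log-likelihood for this density, restricted to the
clamped/floored parameter boxes, so monotonicity of the likelihood is
preserved (a decrease beyond 1e-8 raises an internal error). Components
whose effective count falls below 1e-6 are dropped with a warning and
weights renormalized; N_m can therefore shrink but never grow during
refinement. Convergence is declared when |ΔL| < 1e-6 (absolute change in
the monotone quantity being optimized), with a 500-iteration cap.

## Synthetic data

The generator emulates a two-regime simulation design with equal-size
clusters and n_r = n_e = 20:

- **tight**: p_mj ∈ {0.9, 0.1}, σ = 0.01 — well-separated clusters;
- **noisy**: p_mj ∈ {0.9, 0.4}, σ = 0.3 — overlapping clusters.

Each cluster's Bernoulli profile picks the high/low value per variable with
probability ½, and its means are uniform on [−1, 1] (any order-1 spread
separates tight clusters; for σ = 0.3 it produces the intended partial
overlap). Profiles are redrawn (up to 1000 tries) until all clusters are
pairwise distinct. Sampling is stratified — exactly cluster_size points per
component — not multinomial, matching the equal-size design. What this
generator does *not* emulate: unequal cluster sizes, correlated continuous
variables, missing values, outliers, or variables irrelevant to all
clusters; recovery results on it therefore demonstrate correctness of the
fitting machinery, not robustness to real-data violations of the model.

Recovery is scored by the difference in cluster number and the adjusted
Rand index (pair-counting form, implemented in-package and cross-checked
against scikit-learn in the tests).

Observed behaviour on this design, recomputed by `scripts/acceptance.py`
and the acceptance tests: with λ = 2 the search plus EM recovers the
generating partition exactly (Δk = 0, ARI = 1) in ≥ 8/10 seeds at 100 and
200 points; on a fixed 500-point tight dataset the median cluster count is
non-increasing as the penalty grows from λ = 1 through Hannan–Quinn and
BIC to CAIC — the strong N-dependent penalties collapse toward few
clusters, a search failure (the true solution still scores better), which
is the known weakness of annealing on surfaces dominated by the penalty
term.

## Preprocessing

- Binding p-values binarize at p < 0.001 (strict).
- Expression rows z-score to mean 0, sample (n−1) SD 1; constant rows are
  an error naming the entity. (Population SD is used in model fitting,
  sample SD in normalization and feature selection — MLE consistency in
  the likelihood, conventional statistics outside it.)
- Factor preselection: ρ is the 95th percentile of Pearson correlations
  over all entity pairs (computed once, before any factor subsetting); a
  factor's observed proportion is the fraction of bound-pair correlations
  strictly above ρ; the empirical p compares against 1000 random same-size
  entity sets drawn without replacement, with the add-one estimator
  (1 + hits)/(1 + n_random) and the conservative ≥ tie rule, so p is never
  0; retained iff p < 0.1. Factors binding < 2 entities are auto-rejected.
- Entities bound by no retained factor are dropped.
- Tumour filters: mutations recurring in ≥ 2 samples are kept *first*,
  then samples with no remaining mutation are dropped (the order matters
  and is fixed). Feature selection ranks features by |CV| and by SD and
  keeps the top k = 500 by mean rank; near-zero-mean features get the
  maximum CV rank (their CV is numerically unstable but they are
  certainly variable); ties break by SD rank then column order. The
  "rank-based" statistic is read as rank *combination*, not statistics on
  ranked data — the other reading of an ambiguous phrase.

## Reporting

A cluster is **clear** when its members' average pairwise expression
correlation strictly exceeds 0.5 and at least one binary variable's
probability strictly exceeds 0.5. Singletons are never clear (pairwise
correlation undefined). Each (factor, clear cluster) pair above the
binding threshold becomes one edge in a three-column TSV (source, target,
weight), reconstructible from the parameter table and the report alone.

## Problem sizes and defaults

The simulation-study drivers use 100–500 points (clusters of 10–20,
n_r = n_e = 20), 10 seeds for recovery and 5 for penalty sweeps — sizes at
which the designs' behaviour is already unambiguous. Annealing schedule,
floors, thresholds, restart count, EM tolerance and all generator
parameters are keyword-configurable; defaults are stated above and in the
docstrings.

## Known limitations

- Continuous variables are conditionally independent given the component
  (diagonal covariance); correlated features inflate the apparent cluster
  count.
- No missing-data mechanism: inputs with missing cells are rejected.
- The annealer offers no optimality guarantee; for strong penalties it
  demonstrably under-splits (see above). Restarts mitigate but do not
  remove this.
- Ordinal/nominal variables are out of scope; binaries only.
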