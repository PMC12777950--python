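# Methods

## Setting and estimands

Each unit carries potential outcomes Y(0), Y(1), a binary treatment T and
covariates **X**; only Y = (1−T)·Y(0) + T·Y(1) is observed. Under strong
ignorability (treatment independent of the potential outcomes given **X**,
with positivity) the average treatment effect τ = E[Y(1) − Y(0)] and the
effect on the treated τ_A = E[Y(1) − Y(0) | T = 1] are identified by
adjusting for **X**. The package adjusts by *stratification*: a partition
S₁,…,S_J of the covariate space is built from **X** alone — never from T
or Y, which is what keeps the within-stratum contrasts interpretable —
and effects are estimated stratum by stratum.

With n_j units in stratum j (n_1j treated, n_0j control), arm means
Ȳ_1j, Ȳ_0j and unbiased arm variances s²_1j, s²_0j:

    τ̂  = Σ_j (n_j/n) (Ȳ_1j − Ȳ_0j)
    σ̂² = Σ_j (n_j/n)² (s²_1j/n_1j + s²_0j/n_0j)

For the treated-population effect the control mean is reweighted by the
stratum odds w_j = (n_1j/n_1)/(n_0j/n_0):

    τ̂_A  = Σ_j (n_j/n) (Ȳ_1j − w_j Ȳ_0j)
    σ̂²_A = Σ_j (n_j/n)² (s²_1j/n_1j + w_j² s²_0j/n_0j)

Note the τ̂_A weights are n_j/n rather than the ATT-conventional n_1j/n_1;
this form is implemented as is. When treatment prevalence is constant
across strata w_j ≡ 1 and the two estimators coincide. Inference is Wald:
z = τ̂/σ̂, two-sided normal p-value, τ̂ ± z_{1−α/2}·σ̂ intervals (default
α = 0.05). The same point estimate also solves a per-unit estimating
equation; an independently coded root-finder for it serves as a
cross-check in the test suite, not as the production path.

## Strata builders

**CEM coarsening.** Each continuous covariate is cut into M equal-width
bins over its observed range (last bin right-closed; default M is
Sturges' count ⌈log₂ n⌉ + 1); categorical covariates keep their levels.
Strata are the occupied combinations of coarsened codes, so J ≤ ∏ M_j.
Fully deterministic. Equal-width binning is the common software default;
any data-independent rule would do, since the binning never looks at T
or Y.

**k-means quantization.** The covariate rows (z-scored; categorical
columns one-hot encoded first) are quantized into k cells by Lloyd
iteration with k-means++ seeding, 10 restarts, 300-iteration cap (via
scikit-learn). The within-cluster sum of squares is the empirical
quantization error and is recorded as the builder objective. Empty cells
are dropped and labels compacted. Standardization matters because the
Euclidean objective is scale-sensitive; it can be disabled.

**Random-forest proximity.** A synthetic contrast sample of the same
size is drawn by resampling each covariate column independently from its
empirical marginal, which preserves marginals but destroys the joint
dependence. A random forest is trained to discriminate observed from
synthetic; proximity(i,i′) is the fraction of trees in which units i and
i′ share a terminal node, and units are clustered by Ward agglomeration
on √(1 − proximity), cutting the dendrogram at k strata. Defaults: 500
trees, minimum terminal-node size 5 — fully grown trees memorize the
observed/synthetic labels and drive all proximities toward zero, leaving
the distance matrix uninformative; a modest leaf size restores contrast.
One seed drives the synthetic draw and the forest. The synthetic-class
size, tree count, leaf size and cut height are genuinely open choices
and are all exposed as parameters.

## Pruning

Strata lacking a treated or a control unit (more generally, fewer than
`min_per_arm` per arm) cannot support a contrast and are dropped, with
reasons recorded and a logged warning giving the discarded fraction. The
weights are renormalized over retained strata, so the estimand becomes
the effect on the retained subpopulation — the usual matched-sample
convention. Treated-only strata are likewise dropped for the ATT
(restriction, not extrapolation of the missing control surface). With
`min_per_arm = 1` a retained singleton arm has no variance of its own;
it borrows the pooled within-arm variance across retained strata, and a
warning recommends `min_per_arm = 2`.

## Finite-J bias correction

At fixed J the estimator is biased by residual within-stratum
confounding; the bias vanishes as stratification refines. By analogy
with simulation extrapolation in measurement-error modelling, the effect
is estimated on a grid of strata counts (default 5, 10, 20, 40, 80,
truncated at the largest count still retaining ≥ 90% of units after
pruning, with at least three points kept), a straight line τ̂_J ~ a +
b·(1/J) is fit by ordinary least squares using *realized* post-pruning
counts J_used, and the intercept — the prediction at 1/J = 0 — is the
corrected estimate. The variance estimates are extrapolated with the
same device, floored at 10⁻⁶ times the smallest observed variance so the
reported SE stays positive; extrapolating the variance is itself a
modelling choice, and the prediction-SE alternative can be computed from
the returned grid. Grid points receive independent seed streams spawned
from the master seed. J = 1 is excluded from grids (a single mandatory
point at 1/J = 1 dominates the leverage). The 1/J scale is exact when
the per-stratum bias scales like the quantization distortion in two
effective dimensions (distortion ~ J^(−2/d)); in one dimension the decay
is faster than 1/J and the linear extrapolation overshoots slightly —
visible in the curved 1-D scenario below, where the corrected estimate
retains a small negative bias that is still an order of magnitude below
the uncorrected one.

## Synthetic benchmarks

The generator draws **X** from a known joint (equicorrelated Gaussian
continuous columns plus independent categorical columns), assigns T ~
Bernoulli(expit(γ₀ + γᵀZ)) on the numeric feature view Z, and builds
Y(t) = μ_t(Z) + Normal(0, σ_ε) (or Bernoulli through a logit link for
risk-difference analyses). Ignorability and positivity hold by
construction, and every dataset carries its true ATE (closed form for
polynomial μ on Gaussian outcomes, 10⁶-draw Monte Carlo with recorded SE
otherwise) and true ATT (Monte Carlo, propensity-weighted).

Shipped scenarios (σ_ε = 1 unless noted):

- `null` — μ₁ = μ₀ = X₁ + X₂, γ = (0.15, 0.15); τ = 0.
- `constant` — μ₁ = μ₀ + 2, γ = (0.5, 0.5); τ = 2.
- `linear` — the benchmark: μ₀ = X₁ + X₂, μ₁ = μ₀ + 1 + 0.5·X₁,
  X standard bivariate normal, γ = (0.15, 0.15); τ = 1.
- `curved` — one covariate, μ₀ = X + X², μ₁ = μ₀ + 2, γ = 1.5; τ = 2.
  Strong confounding on a curved surface makes the fixed-J bias large
  and cleanly measurable.
- `discrete` — four binary confounders, Bernoulli outcomes via a logit
  link: a categorical-only risk-difference setting.

The `linear` (and `null`) propensity slope 0.15 is calibrated so that at
the benchmark design — n = 2000 with K = 50 k-means strata — the
residual stratification bias (≈ ½·γᵀΣ_within(b₁+b₀) ≈ 0.013) is small
relative to the sampling SE (≈ 0.05): the benchmark's purpose is to
exercise the variance formula and its CI at a design where the
stratification has essentially removed confounding. Stronger confounding
(e.g. slope 0.5) leaves a bias comparable to the SE at K = 50 and is the
regime the `curved` scenario and the bias correction target instead.

What the generator does *not* emulate: unmeasured confounding (the
estimators assume ignorability; nothing here can detect its failure),
real covariate distributions such as the heavy-tailed mixed-type case
mix of clinical registries, missing data, or treatment effects on the
propensity scale. Passing benchmarks therefore validate the estimator
algebra, its variance, and the bias-correction mechanics — not
robustness to violations of the identifying assumptions.

## Simulation design sizes

Replicated studies use n = 2000 with 500 replicates for coverage (MC SE
of a 95% rate ≈ 0.01) and 200 replicates for the bias-correction
comparison; the consistency sweep uses n ∈ {250, …, 4000} with J = ⌈√n⌉
and replicate counts decreasing in n so the Monte-Carlo error of the
mean bias stays well below the bias differences being compared. All
master seeds are fixed; per-replicate streams are spawned with
`numpy.random.SeedSequence`.

## Numerical choices and edge cases

- Unbiased (n−1) arm variances; a degenerate constant outcome yields
  τ̂ = 0, σ̂² = 0 and a point CI with p = 1.
- σ̂ = 0 with τ̂ ≠ 0 reports p = 0 and a degenerate CI at τ̂.
- k-means with fewer distinct covariate rows than k falls back to one
  stratum per distinct row with a warning.
- Proximities are clipped into [0, 1] before the √(1−p) transform;
  Ward linkage runs on the condensed distance matrix, ties broken by
  scipy's deterministic ordering.
- Extrapolation refuses fewer than three distinct realized strata
  counts; grid points where estimation is impossible are dropped with a
  warning.
- The L1 balance statistic ½ Σ_j |n_1j/n_1 − n_0j/n_0| is computed on
  the unpruned assignment: its endpoints (0 = identically distributed
  arms, 1 = mutually exclusive strata) are only meaningful before
  single-arm strata are removed.

## Known limitations

- The ATT estimator uses the n_j/n stratum weights as given above;
  users expecting the n_1j/n₁ convention should note the difference.
- The linear-in-1/J extrapolant is a first-order device; no quadratic or
  nonparametric extrapolants, and no bootstrap SE for the corrected
  estimate.
- No propensity-score subclassification (strata built from an estimated
  score depend on T and fall outside this framework), no regression
  adjustment within strata, no multi-valued treatments, no missing data.
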