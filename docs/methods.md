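# Methods

## Model and null data-generating process

The analysis model is the random-intercept linear mixed model for a
balanced two-arm cluster randomized trial,

    Y_ij = β0 + β1 x_i + b_i + ε_ij,      i = 1..K,  j = 1..N,

with independent cluster intercepts b_i ~ N(0, σ_b²) and residuals
ε_ij ~ N(0, σ²), and a cluster-level treatment indicator x_i (0 for
clusters 1..K/2, 1 for the rest).  Data are generated from the null
restriction of this model, Y_ij = b_i + ε_ij: the treatment indicator is
carried but plays no role, so every rejection downstream is a Type I
error.  The intraclass correlation is ρ = σ_b²/(σ_b² + σ²); the design
effect (N−1)ρ + 1 summarizes how much clustering inflates the sampling
variance of β̂1.

The generator draws the K standard-normal intercepts first, then the K·N
residuals, and scales by √σ_b² and √σ², in a fixed cluster-major row
layout.  Consequences that the tests rely on:

- **Determinism.** A `DesignConfig` (including its seed) fully determines
  the dataset.  In simulations each replicate owns a pre-assigned stream
  `SeedSequence(master_seed, spawn_key=(condition_index, replicate_index))`,
  so conditions can be rerun or parallelized in any order without changing
  a single draw.
- **Scale equivariance.** (σ_b², σ²) → (cσ_b², cσ²) multiplies y by √c —
  bit-exactly when c and √c are powers of two, to one rounding otherwise.
  This underpins the scale-invariance checks below.

## Fitting: closed forms for the balanced design

Writing τ = σ² + Nσ_b², the likelihood of balanced data factorizes through
the one-way ANOVA sufficient statistics

    SSW = Σ_ij (y_ij − ȳ_i)²,   SSB = N Σ_i (ȳ_i − ȳ_arm(i))²,

with MSW = SSW/(K(N−1)) and MSB = SSB/(K−2).  Because the clusters are
balanced, the GLS fixed-effect estimates do not depend on the variance
components: β̂1 is the difference of arm means under both ML and REML, and
SE(β̂1) = √(4τ̂/(KN)).

- **REML** (interior): σ̂² = MSW, σ̂_b² = (MSB − MSW)/N.  When MSB < MSW the
  unconstrained σ̂_b² would be negative; it is truncated to 0 and σ̂² refit
  as the pooled residual variance about the arm means (divisor KN − 2),
  with a `boundary` flag — the behaviour of standard mixed-model software.
  A numerical tie MSB = MSW is treated as interior (the two definitions
  coincide there).
- **ML**: σ̂² = SSW/(K(N−1)), τ̂ = SSB*/K with SSB* taken about the fitted
  cluster-level means (arm means for the full model, the grand mean for
  the intercept-only comparison model), same truncation rule (ML boundary
  divisor KN).
- **Log-likelihoods** include all constants; the REML criterion profiles
  the fixed effects and includes log|X'V⁻¹X|.  Conventions were chosen to
  match lme4 exactly (verified to 1e−6 in the test suite, and to printed
  precision on spot checks), so likelihood differences are comparable
  across implementations.  Only ML likelihoods feed the LRT; the REML
  value is reporting only.

The closed-form fits never involve an optimizer and cannot fail to
converge on valid input; the simulation engine still counts and excludes
hypothetical failures and aborts a condition if they exceed 1% of
replicates, treating any failure as a defect signal rather than noise.

`numeric_oracle_fit` is an independent verification path: dense-matrix
likelihood evaluation with the fixed effects and σ² profiled out, and
bounded scalar minimization over θ = σ_b²/σ² on [0, 1e8] (xatol 1e−10,
then Newton polish on a complex-step derivative of the same profiled
deviance, since derivative-free search alone is limited to ~√ε precision
by curvature flatness).  It shares no closed forms with the main path and
agrees with it to ~1e−15 relative; it is used only in tests.

## Inference

All tests are two-sided at a configurable α (default .05).

- **Wald**: t* = β̂1/SE(β̂1) against t with DF residual (KN − 2),
  between-within (K − 2, the cluster-level partition of the residual DF,
  equivalent to the one-way ANOVA decomposition here), Satterthwaite, or
  ∞ (standard normal).
- **Satterthwaite DF** = 2·V̂ar(β̂1)²/V̂ar[V̂ar(β̂1)].  The denominator comes
  from the delta method with the inverse *expected* REML information of
  (σ̂_b², σ̂²), assembled in the orthogonal (σ², τ) parametrization where
  the restricted likelihood splits into independent χ² pieces on K(N−1)
  and K−2 DF.  In this design the DF collapse to K−2 for interior fits;
  boundary fits degenerate to an iid regression and yield KN−2.  That
  dichotomy is why the Satterthwaite error rate is always bracketed by the
  between-within and residual choices.  The delta-method code is the
  implementation; the K−2 / KN−2 closed forms serve as test oracles.
- **Kenward-Roger** is exposed as an alias of Satterthwaite: with a single
  cluster-level treatment effect and a random intercept the two DF
  coincide.  No covariance inflation is implemented, so the alias is
  documented as invalid for more general designs.
- **LRT**: λ = −2(ℓ0 − ℓ1) from two ML fits, against χ²₁ (one-parameter
  difference; the tested parameter is a fixed effect, not on a boundary,
  so no mixture correction applies).  λ is clamped at 0 (it can go
  negative only by rounding, observed ≲1e−10); REML fits are rejected
  because restricted likelihoods are not comparable across fixed-effect
  structures.
- **Cluster-means t-test**: pooled two-sample t on the K cluster means,
  DF = K−2.  Its reference distribution is exact under this balanced null,
  which makes it the calibration benchmark in the acceptance checks.  When
  σ̂_b² is interior it coincides with the between-within Wald statistic
  (σ̂² + Nσ̂_b² = MSB exactly); at boundary fits the two differ slightly,
  which is the entire gap between their error rates.
- **Boundary fits**: the Wald SE uses the constrained σ̂² with σ̂_b² = 0.

Rejection is p < α strictly; immaterial for continuous p-values but fixed
for determinism.

## Simulation engine

`run_condition` loops replicates (generate → REML fit → two ML fits → six
tests), tallies rejections, the boundary-truncation rate and convergence,
and attaches the binomial Monte Carlo standard error √(t(1−t)/R) and a
normal-approximation 95% interval to each TIE estimate.  `run_grid`
enumerates the Cartesian grid in deterministic (K, N, σ_b²) order; the
position in that enumeration is the condition's seed-tree index, making
grid results independent of scheduling.  Per-replicate p-values can be
retained (`keep_pvalues`) or archived by the CLI as one compressed
long-format CSV per condition.

**Batched TIE and interaction ANOVA.**  A condition's replicates are split
in replicate order into equal batches (default 10), giving batch-level TIE
outcomes whose mean is the overall TIE exactly.  The three-way factorial
ANOVA on these outcomes (factors K, N, σ_b², all categorical; main
effects, two- and three-way interactions) is computed by closed-form
balanced sums of squares and F-tested against the within-cell batch
variance.  Raw proportions are used as the response; a variance-stabilizing
transform (logit or arcsine-√) is a defensible alternative the API leaves
to the caller, since at TIE ≈ .05 with 1,000-replicate batches the binomial
variance is nearly constant across cells.

## Defaults and problem sizes

The generator and grid defaults are the study conditions themselves:
K ∈ {10, 20, 40, 100}, N ∈ {3, 10, 20, 50}, σ_b² ∈ {0.001, 0.01, 0.02,
0.05, 0.1, 0.2, 0.5}, σ² = 1 (112 conditions), 10,000 replicates, α = .05.
σ² is pinned at 1 because every test statistic is invariant to the overall
variance scale — only ρ matters — which the suite verifies directly.

The test suite uses smaller problem sizes chosen for tight turnaround at
adequate power: the calibration check runs the full 10,000 replicates at
one condition; the directional pattern checks use 2,000 replicates on an
8-condition subgrid K ∈ {10, 20} × N ∈ {3, 50} × σ_b² ∈ {0.001, 0.5}
(binomial tests there have power ≈ 1 for the ≥ 3-percentage-point
departures involved); variance-component recovery uses 2,000 replicates at
K = 100, N = 50.  Estimates at these sizes carry Monte Carlo SEs of
0.002–0.010 on a proportion — adequate for the qualitative claims tested,
coarser than the full default run.

## What the synthetic data do and do not show

The generator reproduces the idealized design the theory addresses:
Gaussian outcomes, exactly balanced clusters and arms, a true null, no
covariates, a single level of clustering.  Passing tests therefore
demonstrate correctness of the estimators and reference distributions
under that model, and the real finite-sample behaviour of the tests within
it.  They do not speak to unbalanced cluster sizes (known elsewhere to
inflate error rates), non-Gaussian outcomes, covariate adjustment,
repeated measures, or ICCs that differ by arm — all outside this package's
scope, as is power under β1 ≠ 0.

## Numerical notes and limitations

- Scale invariance of test results holds bit-exactly for the Wald family
  and the cluster-means t under power-of-two scalings of y; for arbitrary
  scalings, and for the LRT under any scaling (its log terms do not
  commute with exact scaling), invariance holds to machine rounding
  (≲1e−12 relative), which the tests assert.
- The Satterthwaite delta path evaluates exactly, not by numeric
  differentiation; its agreement with the K−2 / KN−2 closed forms is at
  rounding level (asserted at 1e−6).
- Results CSVs are written with full float repr via pandas, so a manifest
  rerun is byte-identical.
- The pseudorandom generator (numpy PCG64 via `default_rng`) and draw
  order are this package's own choices; TIE estimates are insensitive to
  them, but per-replicate draws will not match other software's streams.
- `DesignConfig` requires K ≥ 4 and even, N ≥ 2, σ² > 0: two clusters per
  arm and two subjects per cluster are the minimum for both variance
  components to be estimable.
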