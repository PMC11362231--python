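# Methods

## Model and hypotheses

A two-arm randomized trial is a vector of continuous outcomes Yᵢ, a
binary assignment Aᵢ ∈ {0, 1} with at least two units per arm, and
optional continuous pretreatment covariates Xᵢ.  In potential-outcome
terms, Yᵢ = Aᵢ·Yᵢ(1) + (1 − Aᵢ)·Yᵢ(0), and the tested null is the
sharp constant-effect hypothesis

    H₀: Yᵢ(1) = Yᵢ(0) + τ  for all i.

Under H₀ and randomization, the treated-arm outcome distribution is
the control distribution shifted by τ, so the two arms share a
variance, have parallel empirical CDFs after a shift of τ, and have a
flat quantile-treatment-effect curve τ(q) ≡ τ.  Each test targets one
of these consequences.  All tests assume independent units (no
interference) and complete randomization; the parametric tests
additionally assume normally distributed outcomes within arms.

## Test statistics and estimation

**Location–scale regression (`t_gamma`).**  y ~ N(Xβ, exp(γ₀ + γ₁A));
the mean design X is intercept + treatment (+ covariates if requested),
the log-variance design is intercept + treatment.  The fit is by
restricted-likelihood (REML) scoring: iterate weighted least squares
for β, then a Fisher-scoring step for γ with score
½ Zᵀ(e²/σ² − (1 − h)) and information ½ Zᵀdiag(1 − h)Z, where h is the
weighted leverage.  The leverage correction makes the saturated
(no-covariate) fit reproduce the n−1 sample variances exactly, so
exp(γ̂₁) equals the sample-variance ratio and
SE(γ̂₁) = √(2/(n₁−1) + 2/(n₀−1)).  Convergence tolerance 1e-12 on the
scoring step, at most 100 iterations; failure raises with the full
iteration trace.  The test is two-sided normal on z = γ̂₁/SE.

**Two-group likelihood ratio (`t_lr`).**  Free per-arm means (and
covariate slopes) under both models; variances free vs. constrained
equal.  Because the mean fits separate by arm under either variance
structure, per-arm OLS is the ML mean fit and the statistic has the
closed form n₀·log(s²ₚ/s²₀) + n₁·log(s²ₚ/s²₁) with ML (n-denominator)
variances and s²ₚ their count-weighted pool; referred to χ²₁.  Tiny
negative values from rounding are clipped to zero.

**Random-coefficient Wald test (`t_beta`).**  The treatment slope
varies across units: Var[y|A] = A·σ²ᵤ + σ²ε.  ML fit by Fisher
scoring with step-halving to keep both arm variances positive; σ²ᵤ is
deliberately *unconstrained in sign* and tested two-sided, which
reproduces the documented conservatism of this test (the saturated
estimate is the ML variance difference, which is negative half the
time under the null, and the Wald reference ignores the boundary).
The standard error comes from the full observed information over
(β, σ²ᵤ, σ²ε) at the optimum.

**Randomization engine.**  Complete-randomization draws: each of B
re-assignments places exactly n₁ units in the treated arm.  p is the
strict exceedance fraction p = B⁻¹ Σ I(Tⱼ > T_obs).
Exceedance comparisons carry a relative tolerance of 1e-9 so that
exact-arithmetic ties (the observed assignment itself, or the mirror
relabeling of a symmetric statistic) are classified as ties regardless
of evaluation order.  Exhaustive enumeration replaces sampling when
requested and the assignment count is at most 10⁵.  A constant
randomization distribution (e.g. an all-equal outcome) yields p = 0
and a degeneracy warning.

*Tie rule.*  For the variance and mean statistics ties have measure
zero and the strict rule is used.  The KS distance, however, lives on
the lattice {|i/n₁ − j/n₀|}, so draw-vs-observed ties are common, and
the strict rule is materially anti-conservative (measured ≈ 0.09
type-1 error at n = 25 per arm under a normal null).  The KS-based
tests therefore default to tie-inclusive counting (≥), which restores
the expected slightly-conservative behavior; both rules are available
via `FrtSettings.tie_inclusive`.

*Variance-ratio symmetrization.*  The raw ratio s²₁/s²₀ is one-sided
(only treated-arm inflation is extreme).  The FRT default symmetrizes
to max(T_V, 1/T_V), making the ratio test two-sided like the absolute
variance difference; the two then agree closely in power, and the
symmetrized version matches the operating characteristics reported
for this family of tests.  `symmetrize=False` restores the one-sided
statistic.

**Shifted-KS plug-in tests.**  T_SKS(δ) = sup_y |F̂₀(y) − F̂₁(y + δ)|,
computed exactly over the union of jump points (equivalently, the
two-sample KS distance between the control sample and the treated
sample minus δ).  `frt_pi` imputes the science table at τ̂ (the mean
difference) and, in every draw, rebuilds outcomes from the table and
re-estimates the shift from the drawn data — T_SKS is a *statistic of
the randomized dataset*, so its plug-in shift must be recomputed; the
randomization distribution would otherwise be misaligned with the
observed value.  `frt_ci` repeats this with the science table imputed
at each of 150 equally spaced effects spanning the 99.9 %
normal-approximation (Neyman) interval for τ̂ and reports the maximum
p over the grid; the observed statistic is the same at every grid
point, only the null draws change.  No Berger–Boos-style coverage
allowance is added to the maximum p.  For simulation runs an
early-stop option abandons the grid scan (ordered from τ̂ outward,
where p peaks) once the running maximum reaches α; the decision is
unchanged and the p-value is then reported as a lower bound with a
flag.

**Quantile-process subsampling (`t_sub`).**  τ̂(q) is the treatment
coefficient of a quantile regression at level q.  Without covariates
that regression separates by arm and its solution is the difference of
the arms' check-loss-minimizing order statistics x₍⌈mq⌉₎, which is
computed directly; with covariates, statsmodels' iteratively
reweighted quantile regression is used.  The statistic is
T_sub = max_q |τ̂(q) − τ̂| over a default grid q = 0.10(0.05)0.90 —
extreme quantiles are excluded because subsamples of b ≈ 20 cannot
estimate them.  Inference: draw 500 subsamples of b = 20 units without
replacement (redrawing, with a log entry, any subsample whose arm has
fewer than 2 units), compute each subsample's deviation process
recentered at its own ATE *and* at the full-sample deviation process
(the standard subsampling recentering when the null may be false —
without it the alternative's signal inflates the reference
distribution and the test loses most of its mid-sample power), and
compare √b-scaled subsample maxima against the √n-scaled observed
statistic.  `recenter="own"` disables the process recentering.

**Covariates.**  The parametric tests take covariates as additional
mean-model predictors.  The FRT and quantile tests use residualization:
a single pooled OLS of outcome on intercept + covariates (treatment is
*not* a regressor, so the arm contrast survives in the residuals),
after which the chosen test runs on the residuals.  Rank transforms
use pooled ranks 1..N with average ranks for ties; missing values are
rejected at read time.

## Synthetic-data generator

`generate_trial` draws Y(0) = ε from a standard normal, a t with 5 df,
or a log-normal with meanlog 0 and sdlog 1; with a covariate,
Y(0) = 0.30·X + ε with X standard normal (implying corr(X, Y(0)) =
0.30/√1.09 ≈ 0.287 in the normal case).  The unit effect is
τᵢ = τ + σ_τ·Y(0), so Y(1) = (1 + σ_τ)·Y(0) + τ: heterogeneity is a
pure scale change of the control outcome (variance ratio (1 + σ_τ)²,
e.g. 1.5625 at σ_τ = 0.25), plus a mean shift that is nonzero even at
τ = 0 whenever E[Y(0)] ≠ 0 (log-normal: 0.5·e^½ ≈ 0.824 at σ_τ = 0.5).
Assignment is exactly balanced (n per arm).  Factorial defaults follow
the study design this package reproduces: σ_τ ∈ {0, 0.25, 0.5},
τ ∈ {0, 1}, n ∈ {25, 50, 100, 250} per arm, β_x = 0.30.

The generator emulates independent, exactly balanced, perfectly
measured trials whose heterogeneity is a deterministic function of
Y(0).  Real trials have idiosyncratic (unit-specific, not
Y(0)-driven) effect variation, measurement error, attrition and
covariate-dependent assignment — none of which are modeled — so
passing calibration here demonstrates correctness of the procedures
under the stated model, not robustness to those features.

Seed discipline: every replicate's generator stream is
SeedSequence((scenario seed, replicate index)); every test's
randomization seed hashes (scenario, test name, replicate) through
CRC-32, so any cell of a grid is reproducible in isolation and results
are independent of worker count or execution order.

## Numerical and design choices

- Sample (n−1) variances in all test statistics; ML (n) variances in
  the likelihood-based fits (`t_lr`, `t_beta`), mirroring the
  estimators their models imply.
- The z-based tests reject at |z| > 1.96 for α = 0.05; α is
  configurable and the critical value follows from it (rejection is
  always p < α).
- Quantile-regression ties are resolved by the canonical order
  statistic x₍⌈mq⌉₎ (the solver's vertex in the binary design).
- Degenerate inputs fail loudly: zero within-arm variance (variance
  models), rank-deficient covariate matrices, all-equal outcomes
  (quantile fit), non-binary treatment coding, missing values.
- Simulation-replicate test failures are logged, counted in the
  report's `errors` field, and treated as non-rejections — never
  silently dropped.

Problem sizes in the test suite: deterministic identities run on
trials of 4–60 units; calibration and table-reproduction checks use
1000 trial replications at the study's B values (400 replications for
the grid-maximized KS test, whose per-trial cost is ~150 × 500 KS
evaluations and whose null rejection rate is an order of magnitude
below α); generator-moment checks use samples of 8·10⁵–10⁶ draws with
4-standard-error bands.

## Known limitations

- Rank-based variance FRTs have, by construction, no power against
  purely multiplicative heterogeneity in skewed data: a scale change
  of a log-normal outcome is a location shift on the log scale, and
  pooled ranks are invariant to monotone transforms, so the rank data
  are indistinguishable from a location-shift configuration in which
  both arms' rank variances agree.  Reports elsewhere of substantial
  rank-test power in exactly this configuration could not be
  reproduced by any rank-variance variant we examined (plain,
  normal-scores, science-table-imputed), and the corresponding
  published row appears internally inconsistent; treat rank-variance
  results on skewed data with caution.
- `frt_pi` is mildly liberal for skewed outcomes at small n (the
  plug-in τ̂ is then a poor stand-in for τ); `frt_ci` is the
  conservative alternative.
- `t_beta`'s unconstrained-σ²ᵤ, two-sided Wald convention is one of
  several defensible choices (one-sided or boundary-corrected versions
  would be less conservative); it is fixed here for comparability and
  flagged for sensitivity analysis.
- Subsampling validity is asymptotic in both b and n/b; at n = 50 per
  arm with b = 20 the test remains conservative under the null.
- Multi-arm trials, non-continuous outcomes, stratified or clustered
  randomization, and missing-data handling are out of scope.
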