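# Methods

## Outcome construction

The response is the natural log of an arm's post-treatment HbA1c standard
deviation on the percent scale, plus the small-sample bias correction
`1/(2n − 1)`; its large-sample inverse variance, `2n − 1`, is the
observation weight. Two outcome tracks are carried in parallel: the *raw*
track uses the SD of post-treatment values, the *baseline-corrected*
track the SD of individual change scores (post minus baseline). The two
are analysed separately with identical machinery.

Unit handling: location statistics convert between IFCC and NGSP scales
with the affine map `% = mmol/mol × 0.0915 + 2.15`; dispersion statistics
are translation-invariant, so only the slope applies. All analysis is on
the percent scale.

When an arm does not report an SD directly, it is resolved from the
least-derived statistic available, in fixed priority: SD → SE
(`SD = SE·√n`) → normal-theory CI (`SD = √n·width/(2z)`) → order
statistics. The quantile scenarios (min/median/max, quartiles, and the
five-number summary) use the sample-size-weighted mean combinations of
Luo-type estimators and the closed-form Wan-type SD estimators based on
expected normal order-statistic spacings. The closed forms were chosen
over iterative quantile-matching variants because they are deterministic,
cheap and easily unit-tested; on simulated normal samples of n ≥ 100 they
recover (μ, σ) to within a few percent (range-based scenarios inherit the
larger sampling noise of extremes). Arms with no resolvable SD, no sample
size, or no mean are excluded — never imputed — and logged with a reason
code (`no_sd`, `no_n`, `no_mean`), so input and analysed arm counts always
reconcile.

## The meta-regression model

Arm *a* of trial *j*:

    y_ja = x_jaᵀβ + u_j + ε_ja,  u_j ~ N(0, τ²),  ε_ja ~ N(0, σ²/w_ja)

The fixed part always includes an intercept, the treatment contrast and
the log of the arm's post-treatment mean; the latter adjusts the
variability comparison for the size of the mean treatment effect (larger
mean reductions mechanically change spread). The trial random intercept
absorbs the correlation between arms of the same trial; trials whose arms
all share one treatment level are retained, since they still inform τ²
and the log-mean slope.

Model families built on this core:

* **base** — the treatment-heterogeneity contrast β_t;
* **interaction** — one model per predictor, adding `P` and `P×T`; the
  reported quantities are the predictor's slope in placebo arms (β_P), in
  verum arms (β_P + β_int) and their difference (β_int), each with a Wald
  CI from the fitted coefficient covariance. No multiplicity adjustment
  is applied across the eight predictor models, which are screened one at
  a time; predictors stay on their natural scales (years, %, kg/m²,
  weeks, calendar year) with no centering, so slopes are raw-scale.
* **drug class** — the binary contrast replaced by a class factor with
  placebo as reference; per-class coefficients are the class-vs-placebo
  contrasts. Classes with fewer than two arms are reported but flagged
  unstable.
* **subgroup** — the interaction analysis restricted to trials containing
  a given class, keeping that class's verum arms and those trials'
  placebo arms (all placebo arms of the selected trials; concurrent-only
  selection is not distinguishable from the arm-level data).
* **variance of means** — the sample variance of arm mean HbA1c per
  treatment group with chi-square CIs under normality; a smaller verum
  variance indicates a corridor effect that can mask heterogeneity.

## Estimation and numerics

Restricted maximum likelihood is the default (ML behind a switch). With
λ = τ²/σ² and per-trial covariance `G_j = λ11ᵀ + diag(1/w)`, the GLS β
and σ² have closed-form profile solutions at fixed λ; the Sherman–Morrison
identity reduces every likelihood term to per-trial sufficient statistics
{Σw, Xᵀw, wᵀy}, so one criterion evaluation costs O(trials · p²)
regardless of arm count (a 250,000-arm fit takes well under a second).
λ is optimised on the log scale by a 45-point grid scan over
log λ ∈ [−22, 10] followed by bounded refinement to 1e−12, with the
τ² = 0 boundary always evaluated explicitly; the grid-then-polish scheme
replaces multi-start local optimisation and is robust to the criterion's
occasional flatness near the boundary. σ² is estimated, not fixed at 1,
with per-arm variance σ²/w; under the `2n − 1` weighting of normalised
records σ̂² ≈ 1 is expected and observed in simulation, but it is
estimated so the check is empirical, not assumed. Weights enter the
likelihood only relative to σ²: rescaling all weights by c leaves β̂ and
fit invariant and multiplies σ̂² by c (tested as an identifiability
contract). The alternative large-sample weight `2(n − 1)` is available
via `weight_scheme="2(n-1)"` and is never silently substituted.

Fixed-effect CIs use normal-quantile Wald intervals (`cov(β̂) =
σ̂²(XᵀG⁻¹X)⁻¹`); no denominator-degrees-of-freedom correction is applied,
so third-decimal differences from Satterthwaite-style intervals are
expected. The CI for τ² is profile likelihood: at each fixed τ² the
deviance is minimised over σ² (1-D, log scale), and the 95% bounds are
the roots of the profile drop χ²₀.₉₅(1)/2, found by bisection with a
geometrically expanded upper bracket; the lower bound clips at 0.
Rank-deficient designs are rejected with the offending terms named;
non-convergence of the λ search is flagged on the result, never silent.

Correctness of the fitter is established by dual-oracle tests: on small
fixtures it matches (to ≥6 significant digits in β) both an independent
dense-matrix numerical maximisation of the restricted likelihood and
lme4's `lmer(..., weights = w, REML = TRUE)` run through Rscript.

Descriptive quantiles use linear interpolation between order statistics
(numpy's default); other software's quantile conventions may differ by up
to one order statistic.

## Synthetic data: what it emulates and what it does not

The **individual-level** generator draws baselines N(μ_b, σ_b²) and
additive changes with residual noise; treatment heterogeneity is a
two-point responder mixture (a fraction p of non-responders, the rest
receiving an extra change d), which inflates the verum post-treatment
variance by exactly p(1−p)d² — the analytic identity the tests check
(e.g. p(1−p)d² = 112 on a 12 mmol/mol base gives a 16 mmol/mol verum SD).
Defaults (baseline 66 ± 10 mmol/mol, residual change SD √44 so the
no-mixture post SD is 12 mmol/mol, verum effect −11 mmol/mol) describe a
typical glucose-lowering trial. A `crossover_negative_dependence` flag
generates the counterexample where the person-level treatment effect is
perfectly anti-correlated with the placebo response: arm SDs stay equal
despite genuine heterogeneity. The arm-level pipeline is, by
construction, blind to this case — equal variances are only *indirect*
evidence against heterogeneity — and the flag exists to make that
limitation reproducible.

The **arm-level** generator is the generative twin of the meta-regression
model. Defaults define the study conditions used throughout testing:
174 trials; one placebo arm plus 1–3 verum arms with probabilities
0.6/0.3/0.1 (≈ 2.5 arms/trial, ≈ 435 arms); arm sizes log-uniform on
[5, 8078] to mimic the right-skew of real trial sizes; post-treatment
mean HbA1c lognormal around 8.0% (placebo) and 7.3% (verum) with log-SD
0.08; β₀ = −2.97 (so the placebo median log SD sits near 0.10 given
β_m = 1.476), β_t = 0.037, τ² = 0.112, σ² = 1; trial-level covariates
with realistic locations (age ≈ 57 y, 55% male, BMI ≈ 31 kg/m²,
duration ≈ 7.6 y, baseline HbA1c ≈ 8.2%, 26-week trials, years
1987–2020); and a drug-class mix matching the published corpus's arm
shares. Optional interaction coefficients and per-class SD inflations
inject known signal for recovery tests. All draws flow from one integer
seed; identical configs are bit-identical.

What the generator does *not* emulate: non-normal outcome distributions,
correlation between covariates, dose structure within trials, selective
reporting, or extraction error in the published summaries. Passing
recovery and coverage tests therefore demonstrates the estimator's
correctness under the stated model at the design scale, not robustness of
the scientific conclusion to violations of it.

## Validation summary

The acceptance suite runs, per fresh invocation: dual-oracle equivalence;
500-replicate parameter recovery at the design scale (bias within 3
Monte-Carlo SEs and 95% CI coverage within [0.92, 0.98] for β_t, β_m and
τ², the latter via its profile interval); the bias-correction property
(ln S + 1/(2n−1) closer to ln σ than ln S across 10,000 normal samples at
n ∈ {5, 20, 83}); the responder-mixture variance identity (±0.5 mmol/mol
at 10,000 per arm); and null calibration (β_t CI covers 0 at ≈95% when
β_t = 0). Simulation sizes were chosen to keep Monte-Carlo error well
below each tolerance. `scripts/acceptance.py` recomputes the
back-transformed placebo and verum SDs, estimating β_t from a 100,000-
trial simulated corpus so its Monte-Carlo error (~2·10⁻⁴) is negligible
at the reported 3-decimal precision.

## Known limitations

* Equal arm variances do not rule out treatment heterogeneity (see the
  crossover counterexample above); the method yields indirect evidence.
* The weight `2n − 1` is the inverse variance of the bias-corrected log-SD
  under normality; heavy-tailed outcome distributions would change both
  the bias term and the weight.
* Wald intervals for fixed effects can be slightly anti-conservative at
  small trial counts; the recovery tests calibrate them only at the
  default design scale.
* ANCOVA-adjusted variability reports are out of scope for normalisation,
  as are network comparisons between drug classes and dose–response
  structure.
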