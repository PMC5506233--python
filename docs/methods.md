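# Methods

## Model and estimands

All methods operate on summarized two-sample data: per variant j = 1…J,
estimated associations β̂_Xj (with the risk factor) and β̂_Yj (with the
outcome) and their standard errors, assumed estimated in non-overlapping
samples so the two are independent. Relationships are taken as linear
with no effect modification, and the outcome association decomposes as
β_Yj = α_j + θ β_Xj: θ is the causal effect of the risk factor, α_j the
direct (pleiotropic) effect of the variant. A variant is a valid
instrument iff α_j = 0.

* **Ratio**: θ̂_j = β̂_Yj/β̂_Xj, SE = se(β̂_Yj)/|β̂_Xj| (leading
  delta-method term; uncertainty in β̂_Xj is ignored, consistent with the
  weights below).
* **IVW**: θ̂ = Σ β̂_Yj β̂_Xj w_j / Σ β̂_Xj² w_j, w_j = se(β̂_Yj)⁻²;
  var = σ̂²/Σ β̂_Xj² w_j. Algebraically identical to weighted no-intercept
  least squares of β̂_Y on β̂_X — both routes are implemented and tested
  to agree to 1e−10.
* **MR-Egger**: the same weighted regression with free intercept θ₀.
  Under InSIDE (α_j distributed independently of β_Xj) the slope is a
  consistent estimate of θ and the intercept of the w-weighted mean
  pleiotropic effect; slope var = σ̂′²/Σ w_j (β̂_Xj − β̄_X)², with β̄_X the
  w-weighted mean. For fixed J the exact consistency condition is that
  the w-weighted covariance between α_j and β_Xj vanishes; the simulator
  reports that quantity (`inside_weighted_covariance`) for every dataset
  it generates.
* **Medians**: sort ratio estimates with normalized weights w_(j), form
  cumulative midpoints s_j = Σ_{k≤j} w_(k) − w_(j)/2 and linearly
  interpolate at s = ½. Equal weights reproduce the ordinary median
  (mean of the central pair at even J). Weighted-median weights are the
  inverse first-order ratio variances se(β̂_Yj)²/β̂_Xj²; a second-order
  option adding β̂_Yj² se(β̂_Xj)²/β̂_Xj⁴ exists but is off by default. Ties
  are broken by a stable sort on (ratio, variant id) for determinism.
* **Robust IVW**: the whitened no-intercept regression (x = β̂_X/se_Y,
  y = β̂_Y/se_Y) refitted under Tukey's bisquare ρ with tuning constant
  c = 4.685 (95% Gaussian efficiency). MM-style construction: LAD initial
  slope (the |x|-weighted median of y/x), residual scale fixed at the
  normalized MAD of the initial residuals, then IRLS to |Δθ| ≤ 1e−10
  (max 200 iterations; failure raises with the last iterate). SE by the
  Huber sandwich on ψ. A numerically exact fit short-circuits to the
  least-squares (= IVW) solution, which the bisquare limit attains.
* **Correlated variants**: GLS with Ω_{j1,j2} = se(β̂_Yj1) se(β̂_Yj2)
  ρ_{j1,j2}. Two routes: solve the normal equations with Ω⁻¹, or whiten
  with the inverse Cholesky factor of Ω and run ordinary least squares;
  both are exposed and agree to 1e−10 (a standing cross-check).

## Variance models and inference

`fixed` sets the regression residual scale σ to 1 — the fixed-effect
meta-analysis convention, appropriate when per-variant causal estimates
are homogeneous. `random_multiplicative` estimates σ from the weighted
residuals (df J−1 for IVW, J−2 for MR-Egger) and divides reported SEs by
min(σ̂, 1), i.e. truncates σ̂ below at one: for uncorrelated variants
there is no biological mechanism producing underdispersion, so a
random-effects analysis is never allowed to report a smaller SE than the
fixed-effect one. The untruncated σ̂ is always kept in `sigma_hat`
because underdispersion, when it appears, is itself diagnostic (variant
selection that preferentially picks similar variants — or chance). For
correlated fits the truncation is still applied but a warning notes that
underdispersion can be genuine there. MR-Egger defaults to the
random-effects model (pleiotropy implies overdispersion); when
heterogeneity is absent the two models coincide.

Intervals and p-values default to a t reference with the residual
degrees of freedom, matching standard weighted-regression output; a
normal option exists for large-J work, and is also the automatic
fallback when no residual df exist (J = 1). Median-method SEs come from
a parametric bootstrap (default 10 000 iterations, seeded): β̂_X and β̂_Y
are redrawn from normals centred at the estimates with the reported SEs,
the median recomputed per draw, and the SE taken as the bootstrap SD
with a normal-approximation CI. The `variance_model` label on results
is extended beyond {fixed, random_multiplicative} with `bootstrap`
(medians) and `robust` (robust IVW) so every estimator serializes
uniformly.

## Orientation

Allele codings are arbitrary, and MR-Egger's intercept changes meaning
when any variant is recoded, so variants are orientated to non-negative
β̂_X (pleiotropy defined with respect to the risk-factor-increasing
allele) before an Egger fit; IVW is provably invariant to orientation
and the suite asserts this to 1e−12. Flipping negates both betas (the
ratio is preserved exactly), swaps the allele labels, leaves SEs alone,
and negates the off-diagonal correlation entries of the flipped variant
(recoding an allele negates its allele-count correlations). A variant
with β̂_X exactly 0 cannot be orientated: it is kept with a warning and
excluded from median methods (its ratio is undefined); IVW and Egger
handle it naturally through its zero design contribution. Orientation
is on by default in the CLI and always logged.

## Diagnostics

I²_GX = max(0, (Q_X − (J−1))/Q_X) with Q_X = Σ w_j (β̂_Xj − β̄_X)²
measures instrument strength for MR-Egger; weights default to se(β̂_Xj)⁻²
(the instrument-strength convention) with se(β̂_Yj)⁻² available because
the Egger variance uses those weights — the CLI logs both. Cook's
distances and externally Studentized residuals are the standard WLS
quantities from the weighted hat matrix (verified in tests against an
independent OLS-influence computation on the whitened design); a
leverage of 1 yields an infinite-influence report with a warning, and a
fit that is exact to roundoff reports zero influence rather than ratios
of machine-epsilon residuals. Heterogeneity Q uses se(β̂_Yj)⁻² weights
about the fitted regression, with a χ² reference on the residual df;
Q/(J−1) equals the squared random-effects σ̂ of the IVW fit by
construction. Leave-one-out refits the estimator J times. No automatic
outlier removal is performed anywhere: reports rank variants and print
the conventional annotations (Cook's 4/J, |t| > 3) without enforcing
them.

Degenerate inputs: all-equal β̂_X makes both MR-Egger parameters
non-identified and raises (and gives I²_GX = 0); J < 3 raises for Egger
and the medians; a non-positive-definite correlation matrix within the
1e−8 PSD tolerance is repaired by eigenvalue clipping at 1e−8 with
re-normalization to unit diagonal, under a warning.

## Simulator

Simulation happens at the summary-statistic level: truths are drawn,
observed estimates are truths plus independent normal noise at known SE
levels, and the reported SEs equal those levels. This matches the
estimators' own assumptions (known SEs, independent samples); it does
not emulate individual-level features — finite-sample SE estimation
noise, sample overlap, winner's curse in variant selection, allele
frequency structure, or LD (the correlated module is exercised on
synthetic correlation matrices instead). Passing tests therefore
validate the estimators under their stated model, not robustness to
those real-data complications.

Default conditions: J = 25 variants, true β_X ~ Uniform(0.05, 0.15),
se_x = 0.005, se_y = 0.01, true θ = 0 (null). Pleiotropy scenarios:
α_j = 0 (`no_pleiotropy`); α ~ N(0, 0.004) (`balanced_direct`);
α ~ N(0.01, 0.004) independent of β_X (`directional_direct` — InSIDE
holds); and confounder-mediated pleiotropy, where each variant's
confounder effect γ_j ~ N(0.05, 0.02) feeds both the instrument strength
(β_Xj += 0.5 γ_j) and the pleiotropic effect (α_j = 0.2 γ_j), coupling
the two and violating InSIDE (`via_single_confounder`; the
`via_multiple_confounders` variant draws one independent confounder per
variant, which induces the same per-variant coupling). The path
coefficients 0.5/0.2 are chosen so the induced α has mean 0.01 and sd
0.004 — the same scale as the directional-direct scenario, making the
two comparable; with these values the InSIDE-violating weighted
covariance is λ_X λ_Y var(γ) = 4e−5 > 0, which the simulator's reported
`inside_weighted_covariance` reproduces. Effect scales are desk-scale
choices that make the phenomena visible at J = 25–50, and every one of
them is exposed in `ScenarioConfig`.

`bias_study` derives per-replicate seeds from the master seed by a
stated counter scheme, rep_seed = (master · 1 000 003 + i) mod 2³¹, so
tables are exactly reproducible. It defaults to the fixed-effect
variance model: the generator satisfies that model exactly (known SEs,
no residual heterogeneity under the null scenario), so rejection rates
then read as calibration of the nominal test. The truncated
random-effects procedure is deliberately conservative — max(σ̂, 1)
inflates the SE whenever σ̂ > 1 while the truncation blocks the
compensating deflation — and can be studied by passing it explicitly.
Monte-Carlo studies in the tests and acceptance script use J = 50 and
500 replicates, which puts Monte-Carlo SEs near 0.002 for the Egger
slope (medians use a 200-iteration bootstrap per replicate inside
studies; single analyses default to 10 000). Parameter-recovery checks
run at θ = 0.1: at the default se_x the finite instrument strength
(I²_GX ≈ 0.97) attenuates the MR-Egger slope by ≈3% of θ — a property
of the estimator, not an implementation error — so a small θ keeps that
attenuation well inside the Monte-Carlo tolerance while still
exercising a non-null effect; calibration is checked at θ = 0.

## Known limitations

MR-Egger's weak-instrument (regression-dilution) bias is diagnosed via
I²_GX but not corrected (no SIMEX). Median SEs are bootstrap-only; no
analytic alternative is provided. The robust-IVW sandwich SE is
asymptotic and approximate at small J. Strand/palindrome harmonization
by allele frequency is out of scope (no frequency columns in the data
model), as is estimating LD matrices from reference panels — the
correlation matrix is caller-supplied.
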