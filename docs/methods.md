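# Methods

## Model and estimands

The package works with a 2×2 factorial design for treatments A and B. Each
participant has four potential outcomes Y^{Z_A=a, Z_B=b}, one per joint
assignment, with cell-level parameters p_ab = E[Y^{a,b}] (an event
probability for binary outcomes, a mean for continuous ones; continuous
cells share a residual SD σ). All population-level quantities are
deterministic functions of (p00, p10, p01, p11):

* the conditional (stratum-specific) effect of A in stratum B = b,
* the marginal effect of A when a proportion π of the population receives
  B, computed by mixing cell parameters within each A arm before forming
  the contrast,
* the interaction contrast on a chosen scale,
* the four estimands: effect of A in the absence of B, in the presence of
  B, under usual-practice receipt of B, and the A+B combination vs neither.

Summary measures and link scales are fixed pairs: mean difference and risk
difference use the identity link, risk ratio the log link, odds ratio the
logit link. "No interaction" means the interaction contrast is zero on the
link scale of the measure in use; this convention makes "no interaction"
coincide with a zero coefficient in the interaction regression model.
Ratio-scale values are reported as ratios; their logs are the link-scale
values on which all inference is done.

The usual-practice estimand has a marginal reading (default) and a
conditional one. The conditional reading exists only when the two stratum
effects agree on the link scale; the implementation treats them as equal
when they differ by at most 1e−8 and otherwise raises an explicit
"estimand undefined" error — never a silent number. The marginal reading
stays well defined even when receipt of B depends on A (arm-specific
mixing proportions), which is exactly the regime where the conditional
reading breaks down.

Boundary probabilities (0 or 1) are rejected in the cell-level oracle
rather than continuity-corrected: the oracle must be exact, and corrections
would silently change the estimand.

## Estimators and inference

Four regression models cover the analyses: factorial adjusted
(α, β_A, β_B), factorial unadjusted (α, β_A), multiarm cell dummies
(α, β_A0, β_0B, β_AB with the double-control cell as reference), and the
interaction model (α, β_A, β_B, β_Int). Fitting is delegated to
statsmodels: OLS for continuous outcomes; binomial GLM by IRLS
(tolerance 1e−8, at most 100 iterations) for the logit and log links; and
identity-link least squares on 0/1 outcomes with heteroskedasticity-robust
(HC1) covariance for the risk difference, since the Bernoulli residual
variance depends on the mean. Non-convergence and separation (detected as
|coefficient| > 30 on the link scale or a coefficient SE above 1e3) raise a
named fitting error rather than returning garbage.

Estimand routing follows the factorial/multiarm mapping: factorial always
uses the *adjusted* model (for noncollapsible measures the unadjusted model
targets a marginal quantity tied to the trial's allocation ratio and is
biased for every estimand here; it is exposed solely to demonstrate that
bias). The multiarm strategy uses β̂_A0, β̂_AB − β̂_0B, β̂_AB, and the
π-weighted contrast for the usual-practice estimand, with π a fixed
user-supplied constant contributing no variance. No estimator exists for
the *marginal* odds-ratio usual-practice estimand; results for that
combination carry an explicit note instead of a pretend answer
(g-computation standardization would be the natural extension but is not
implemented).

Inference is Wald on the link scale: normal reference for binary measures,
t with residual degrees of freedom for continuous least squares.
Confidence intervals are back-transformed monotonically, so natural-scale
endpoints are the exact exponentials of link-scale endpoints. When a fit is
numerically noiseless (zero residual variance, SE below 1e−12 relative to
the estimate), the Wald ratio is float noise; such degenerate contrasts
report p = 1 for a numerically null estimate and p = 0 otherwise.

Contrast arithmetic (`linear_combination`) uses the full coefficient
covariance, w'β̂ with variance w'Vw. The interaction model is an exact
reparameterization of the multiarm model (β_A0 = β_A, β_0B = β_B,
β_AB = β_A + β_B + β_Int), verified to 1e−6 on random datasets including
the contrast variances.

## Synthetic-data generator

The generator draws from the potential-outcomes model directly: each
participant's outcome comes from their realized cell's distribution
(Bernoulli(p_ab) or Normal(p_ab, σ)). Assignment mechanisms:

* factorial: Z_A ~ Bernoulli(0.5) and Z_B ~ Bernoulli(0.5) independently.
  Independent coin-flip allocation was chosen over permuted blocks because
  it keeps the oracle targets exact and is asymptotically equivalent;
  1:1 allocation on both factors is the standard factorial design.
* usual practice: Z_A randomized, Z_B ~ Bernoulli(π_{Z_A}) with
  arm-specific receipt probabilities, so A-dependent receipt of B is a
  single parameter away.

Discontinuation is modeled as a per-cell Bernoulli intercurrent event that
shifts the discontinued participant's outcome parameter by a constant
(binary probabilities clipped to [0.01, 0.99]); treatment labels stay
as-randomized, so any analysis of the modified data is treatment-policy by
construction. One consequence worth noting: a discontinuation mechanism
that affects both Z_B = 1 cells equally shifts both arms of the A|B=1
contrast and cancels; only asymmetric discontinuation (e.g. confined to
the A+B cell) moves that estimate, by the mixture-mean amount
(discontinuation probability × shift). The tests check both facts.
Outcomes are shifted, not exposures: there is no dose-response machinery,
which is enough to quantify the treatment-policy vs hypothetical gap but
not to model partial adherence. Death, censoring, rescue medication, and
principal strata are out of scope; estimation under hypothetical,
composite, while-on-treatment, or principal-stratum strategies is not
implemented (the generator could produce the counterfactual outcomes, but
no estimator is provided).

Seeding is strict: every simulation requires an explicit integer seed,
replicate r of a study uses base_seed + r, and the intercurrent overlay
draws from a stream derived from (seed, 1) so it never replays the
allocation draws. Passing tests on these synthetic trials demonstrate
estimator properties under correct randomization and complete follow-up;
they say nothing about confounded real-world data, informative
missingness, or model misspecification beyond the interaction structure.

## Simulation studies

Operating characteristics (bias, empirical SE, mean model SE, coverage,
interaction-test rejection rate) are computed on the link scale, where the
estimators are asymptotically normal; ratio-scale bias would conflate bias
with transformation curvature. Coverage is the fraction of replicate CIs
containing the link-scale oracle. Pass/fail bands in the tests are 3×
Monte-Carlo error (3 × empirical SE / √reps for bias; 3 binomial SDs for
coverage and rejection rates) — the conventional choice, giving ≈0.3%
false-alarm probability per check. Replicates whose fit fails (separation
at small samples) are excluded with accounting; more than 5% failures
aborts the study.

Default study sizes — 500 replicates of n = 2000 for the assumption matrix
and weighted-estimator studies, 1,000 replicates for the two-stage coverage
comparison, 50,000 per cell for the single-trial noncollapsibility check,
400 replicates for the interaction-test type-I-error check — were chosen so
that Monte-Carlo error is an order of magnitude below the effects being
demonstrated (e.g. the factorial bias under a log-OR interaction of 1.5 is
≈0.49 against an MC error of ≈0.005).

The reference binary configuration is the cell-probability set
(0.50, 0.333, 0.091, 0.048): A halves the odds in both strata, B has OR
0.10, there is no log-odds interaction, and the marginal OR at 50% receipt
of B is 0.56. Interaction scenarios perturb the (1,1) cell to impose a
chosen log-OR interaction while leaving the other three cells fixed. The
continuous configuration for the weighted-estimator study uses cell means
(0, 1, 2, 3.5) with σ = 1 — a unit effect of A alone, a B effect, and an
interaction of 0.5, so that the usual-practice oracle genuinely depends on
π — with usual-practice receipt 0.3 (independent case) and (0.2, 0.8)
(A-dependent case).

## Framework conventions

The four-step framework report labels intercurrent-event strategies as
free-text metadata; only treatment policy affects computation. The
concordance rule between the primary (factorial) and sensitivity
(multiarm) estimates is: *consistent* if each link-scale point estimate
lies inside the other's CI (with a 1e−9 relative tolerance so zero-width
noiseless CIs behave), *discordant* if the point estimates lie strictly on
opposite sides of the null, *indeterminate* otherwise. This
operationalizes "results broadly agree"; it is a documented convention,
symmetric in its arguments, not a test with controlled error rates. The
interaction row of the report includes the fold-range between the natural
CI limits as an imprecision diagnostic for ratio measures.

The two-stage procedure (pre-test the interaction at α, then let the test
pick the estimator) is implemented with an explicit `two_stage` tag and
used only to measure its own coverage distortion.

## Known limitations

* No baseline covariates beyond the two treatment factors; no multi-level
  factors or higher-order factorials; no time-to-event outcomes.
* The marginal odds-ratio usual-practice estimand has no estimator here
  (flagged, not guessed).
* Log-binomial (risk-ratio) fits can fail to converge near boundary
  risks; the failure is reported, no automatic fallback is applied.
* The marginal odds ratio is not monotone in π between its endpoint
  values — with a common stratum OR it is attenuated toward 1 in the
  interior and returns to the conditional value at π ∈ {0, 1}; only risk
  difference and risk ratio are monotone in π, and the property tests
  reflect that.
* Monte-Carlo assertions are exact-seeded and therefore reproducible, but
  their bands are calibrated for the default study sizes; shrinking the
  number of replicates widens the true sampling noise relative to the
  bands.
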