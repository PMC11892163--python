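# Methods

## Estimand and estimator

The package targets conditional natural-effect odds ratios for a binary
exposure $A$ (contrast $a=1$ vs $a^*=0$), binary mediator $M$ and binary
outcome $Y$ given covariates $C$, under the usual mediation assumptions:
no unmeasured exposure–outcome, exposure–mediator or mediator–outcome
confounding given $C$, and no mediator–outcome confounder affected by the
exposure. Causal ordering is assumed recursive within each analysis
(exposure precedes mediator precedes outcome); because mediator and
outcome may share a recall window in survey data, both orderings are run
as separate analyses rather than adjudicated.

Estimation is regression-based: weighted logistic models for
$M\mid A,C$ (coefficients $\beta$) and $Y\mid A,M,C$ (coefficients
$\theta$, optionally including an $A{\times}M$ interaction $\theta_3$) are
combined into closed-form odds ratios (see README for the formulas). The
combination is exact for the odds of the counterfactual risks only when
the outcome is rare; see "Rare-outcome approximation" below. The total
effect satisfies $\mathrm{OR^{TE}}=\mathrm{OR^{NDE}}\cdot\mathrm{OR^{NIE}}$
identically, so the decomposition test is a build-correctness check, not a
statistical one. The proportion mediated is
$\log\mathrm{OR^{NIE}}/\log\mathrm{OR^{TE}}$; it is undefined at
$\mathrm{OR^{TE}}=1$ (flagged as NaN, never silently zero) and may fall
outside $[0,1]$ when direct and indirect effects oppose (returned as-is
with a warning).

### Covariate evaluation point

The conditional odds ratios depend on $C$ only through the mediator-model
contribution $\beta_2'c$. By default $c$ is the weighted mean of the
indicator-coded covariate columns in the analysis sample (the convention
of the regression-based mediation software ecosystem); weighted-modal and
explicit settings are selectable. Whether a published analysis conditioned
at covariate means or elsewhere is usually unstated, so this is exposed as
configuration rather than guessed; the choice is recorded in the output
metadata.

### Interaction default

`include_interaction=True` fits the general formulas; turning it off
imposes $\theta_3=0$ and recovers the product-method decomposition. Both
paths are first-class. Simulation-based validation tests use the
no-interaction configuration when the generating model itself has
$\theta_3=0$, i.e. when that estimator is correctly specified.

## Weighted logistic engine

Survey weights enter as frequency-style multipliers of the Bernoulli
log-likelihood (pseudo-likelihood). Fitting is Newton/IRLS with
step-halving, relative deviance tolerance $10^{-8}$, at most 100
iterations; coefficients are invariant to positive rescaling of the
weights. Model-based standard errors are deliberately never reported —
they would be wrong under the design — and all interval estimation goes
through the bootstrap. Separation is flagged when any fitted probability
is within $10^{-8}$ of 0/1 at convergence or any coefficient exceeds 15
in magnitude; the point-estimation path raises on separation while the
bootstrap drops and tallies the replicate. No penalised (Firth) fallback
is provided. Categorical terms are indicator-coded against a stated
reference level (age 18–25, education "high"); sex is never a model term —
analyses are run separately per sex. The engine is cross-checked in the
test suite against statsmodels GLM with frequency weights (agreement to
$10^{-6}$), which serves as an independent oracle only.

## Survey design handling

Descriptive prevalences are weighted ratio estimates; their variance uses
Taylor linearisation over strata and PSUs (with-replacement approximation,
$n_h/(n_h-1)$ stratum factors), and 95% intervals are formed on the logit
scale and back-transformed. Single-PSU strata contribute no variance and
are logged. Group differences are flagged only when two 95% intervals are
disjoint; a shared endpoint counts as overlap. This rule is conservative
by construction and no formal two-sample tests are offered.

The bootstrap honours the design by resampling PSUs with replacement
within strata (original PSU count per stratum, weights carried as-is, not
re-derived); an i.i.d. row bootstrap is available for unclustered data. A
stratum with a single PSU falls back to i.i.d. resampling within that
stratum, logged. Replicate RNG streams derive from
`(seed, replicate_index)` — a contract making replicates independent of
execution order. Intervals are plain percentile intervals with linear
interpolation between order statistics (the dialect is recorded in output
metadata because percentile definitions differ across software); BCa and
studentised intervals are out of scope.

## Synthetic cohort generator

The generator emulates the structure of a national sexual-health survey
whose raw data are not publicly deposited:

* **Covariates.** Six age groups and three education levels drawn
  independently from the published sex-specific marginals.
* **Structural equations.** Exposure, then mediator, then outcome drawn
  from logistic models following the assumed directed acyclic graph, with
  covariates entering all three. Default covariate gradients are mild
  (≤0.25 on the logit scale).
* **Calibration.** All three intercepts are solved (Brent root-finding on
  closed-form marginals enumerated over the finite covariate support) so
  that the marginal prevalences of exposure, mediator and outcome equal
  their published targets exactly in expectation — e.g. lifetime SAE
  14.0% (women) / 2.7% (men), depression 10.7% / 5.6%, heavy tobacco
  7.8% / 12.3%, frequent cannabis 1.0% / 2.6%, hazardous alcohol
  0.7% / 0.9%. Simulated prevalences therefore deviate only by
  Monte-Carlo noise.
* **Effect sizes.** The published analysis does not report structural
  (logit-scale) coefficients, so defaults are the package's choice, fixed
  once: exposure→mediator log OR $=\log 2$, exposure→outcome
  $=\log 3$, mediator→outcome $=\log 2.5$, interaction $=0$. These land
  simulated total and indirect effects in the range of the published
  mediation tables (TE roughly 1.5–7, NIE 1.0–1.5) without claiming the
  study's latent parameters.
* **Nested exposures.** Childhood SAE is a subset of lifetime SAE with
  conditional probability matching the published ratio (3.1/14.0 women,
  0.8/2.7 men); a repeated-SAE flag is drawn at 0.45 given exposure — the
  published tables give no repeated-event prevalence, and 0.45 makes the
  sensitivity contrast well-populated without dominating.
* **Design.** 10 strata × 20 PSUs per stratum, log-normal weights with
  unit mean (σ = 0.5), assigned independently of the substantive
  variables. The real survey's two-stage municipality sampling is not
  replicated; the design exists to exercise design-based code paths, so
  weighted and unweighted targets coincide in expectation.
* **Missingness.** Missing-completely-at-random per column, at the rates
  implied by the published missing counts (e.g. hazardous alcohol 4.6%
  among women, tobacco 0.3%, depression 0%), with the childhood-SAE rate
  capped at 4.9% to keep all defaults under the documented <5% bound
  (the published childhood-item missingness is higher, 11.8% in women).
  MAR/MNAR mechanisms are out of scope, matching the listwise-deletion
  analysis the pipeline applies.

**What the generator does not emulate:** informative sampling (weights
correlated with outcomes), non-response structure, measurement error in
self-reports, and within-PSU correlation of the substantive variables.
Passing recovery and coverage tests therefore validate the estimators
under a correctly specified design-independent data-generating process;
they do not certify behaviour under informative designs.

### Exact oracle

With a binary mediator the counterfactual risk
$P(Y_{a,M_{a^*}}{=}1\mid c)$ is a two-term sum, so the oracle computes
true NDE/NIE/TE odds ratios in closed form at any covariate setting
(modal cell by default; weighted-mean evaluation mirrors the estimator's
default). $\mathrm{OR^{TE}}=\mathrm{OR^{NDE}}\cdot\mathrm{OR^{NIE}}$
holds exactly by construction. The oracle is itself cross-checked against
brute-force Monte-Carlo counterfactual simulation on randomly drawn
parameter sets.

## Rare-outcome approximation

The OR combination formulas are exact only as outcome prevalence → 0. At
the prevalences in scope (0.7–12.3%) the package uses them as published
analyses do, and records outcome prevalence in the estimate metadata so
users can judge the approximation. Measured against the exact oracle at
the default effect sizes: relative error is below 1% at ≤1% outcome
prevalence, ~0.4% at 10.7% prevalence for the default
tobacco→depression cell (the error largely cancels between numerator and
denominator odds), and stays below the documented 5% bound at the highest
prevalence in range (12.3%).

## Validation design and problem sizes

* **Parameter recovery** uses the default tobacco→depression cell at
  n = 200,000 with two fixed seeds, requiring every estimated log-OR
  within 0.05 of the oracle. This cell is chosen on variance grounds: its
  ~21k outcome events give log-TE sampling SD ≈ 0.015, so 0.05 is a real
  but attainable bar, whereas a 1%-prevalence cell has SD ≈ 0.035 and
  would make a fixed-seed check a coin flip.
* **Null behaviour**: with the exposure→mediator path removed, the median
  estimated NIE over 200 cohorts (n = 2,000) is 1 within Monte-Carlo
  error of the median.
* **Bootstrap coverage**: 200 independent cohorts of n = 5,000 with 500
  replicates each (scaled down from the production default of 1,000);
  the 95% NIE interval must cover the oracle truth 90–99% of the time.
* **Calibration**: every published marginal prevalence reproduced within
  3 Monte-Carlo standard errors at n = 10⁶.

## Known limitations

* No four-way decomposition, continuous mediators/outcomes, multiple
  mediators, or sensitivity analysis for mediator–outcome confounding.
* The bootstrap treats the design as given; weights are not re-derived
  per replicate, and finite-population corrections are not applied.
* Listwise deletion is the only missing-data strategy, consistent with
  the analysis the pipeline reproduces; it is inefficient and assumes
  MCAR for unbiasedness.
* The rare-outcome approximation degrades with common outcomes; the
  package reports, but does not correct for, outcome prevalence.
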