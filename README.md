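# survmediate

Counterfactual mediation analysis on the odds-ratio scale for complex
survey data, with a calibrated synthetic-cohort simulator for validation.

## The problem

Epidemiological surveys often ask how much of an exposure's effect on a
binary outcome flows through a binary intermediate — for example, how much
of the association between sexual-assault experience (SAE) and depression
is carried by heavy substance use, and, conversely, how much of the
association between SAE and heavy substance use is carried by depression.
When the survey has weights, strata and clustered primary sampling units
(PSUs), and inference relies on the bootstrap, the pieces rarely live in
one place. `survmediate` packages the whole pipeline for analysts working
with such data: survey-weighted logistic models, the regression-based
counterfactual combination, design-respecting percentile bootstrap,
design-based descriptives, and a simulator with exact ground truth.

## The model

For exposure $A$, binary mediator $M$, binary outcome $Y$ and covariates
$C$, two weighted logistic models are fitted:

$$\text{logit}\, P(M=1\mid A,C) = \beta_0 + \beta_1 A + \beta_2' C$$
$$\text{logit}\, P(Y=1\mid A,M,C) = \theta_0 + \theta_1 A + \theta_2 M +
\theta_3 AM + \theta_4' C$$

and combined into conditional odds ratios for the natural direct effect
(NDE), natural indirect effect (NIE) and total effect (TE), valid when the
outcome is rare:

$$\mathrm{OR^{NDE}} = e^{\theta_1}\,
\frac{1+e^{\theta_2+\theta_3+\beta_0+\beta_2'c}}
     {1+e^{\theta_2+\beta_0+\beta_2'c}},\qquad
\mathrm{OR^{NIE}} =
\frac{(1+e^{\beta_0+\beta_2'c})
      (1+e^{\beta_0+\beta_1+\beta_2'c+\theta_2+\theta_3})}
     {(1+e^{\beta_0+\beta_1+\beta_2'c})
      (1+e^{\beta_0+\beta_2'c+\theta_2+\theta_3})}$$

with $\mathrm{OR^{TE}} = \mathrm{OR^{NDE}}\cdot\mathrm{OR^{NIE}}$ as an
identity, and the proportion mediated

$$\mathrm{PM} = \log \mathrm{OR^{NIE}} / \log \mathrm{OR^{TE}}.$$

Confidence intervals are 95% percentile-bootstrap intervals, resampling
PSUs with replacement within strata (1,000 replicates by default); an
indirect effect is flagged when its interval excludes 1.

Because real cohorts of this kind are typically not public, the
`cohort` module simulates survey cohorts from the assumed causal graph
(covariates → exposure → mediator → outcome) with intercepts calibrated
exactly — by enumeration over the finite covariate support — to published
marginal prevalences, and computes the *exact* counterfactual odds ratios
implied by the generating parameters. Every estimator in the package is
validated against that oracle.

## Worked example

```python
import survmediate as sm

params = sm.default_params("female", mediator="heavy_tobacco",
                           outcome="depression")
cohort, truth = sm.generate_cohort(params, n=10_000, seed=7)

spec = sm.MediationSpec("sae_lifetime", "heavy_tobacco", "depression")
est = sm.bootstrap_mediation(cohort, spec, sm.SurveyDesign(),
                             sm.BootstrapConfig(n_replicates=500, seed=11))
```

This prints, via `examples/04_bootstrap_ci.py`:

```
OR_TE    3.016  95% BCI [2.565, 3.517] *
OR_NDE   2.892  95% BCI [2.447, 3.365] *
OR_NIE   1.043  95% BCI [1.016, 1.082] *
PM         3.8%  95% BCI [1.4%, 7.2%]

replicates kept: 500/500 (dropped: none)
* = interval excludes an odds ratio of 1
```

The exposure roughly triples the odds of depression (TE = 3.02); a small
but significant share (PM = 3.8%) flows through heavy tobacco use
(NIE = 1.04, interval excluding 1). The generator's exact truth for this
parameter set is TE = 3.16, NDE = 2.97, NIE = 1.07 at the modal covariate
cell, so the estimates are in range at n = 10,000.

The `examples/` directory holds one short script per capability
(simulation, descriptives, single-cell estimation, bootstrap, the full
analysis grid, and a standalone proportion-mediated calculator). A thin
CLI mirrors the pipeline: `survmediate simulate | describe | mediate | pm`.

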