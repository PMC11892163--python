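"""Counterfactual mediation on the odds-ratio scale.

Two weighted logistic regressions — one for the binary mediator given
exposure and covariates, one for the binary outcome given exposure, mediator,
their optional interaction and covariates — are combined into conditional
odds ratios for the natural direct effect (NDE), natural indirect effect
(NIE) and total effect (TE), using the closed-form regression combination
valid for a dichotomous mediator when the outcome is rare. Writing theta for
the outcome-model and beta for the mediator-model coefficients, at covariate
setting c and contrast a=1 vs a*=0:

    OR_NDE = exp(theta1 (a - a*))
             * (1 + exp(theta2 + theta3 a  + beta0 + beta1 a* + beta2'c))
             / (1 + exp(theta2 + theta3 a* + beta0 + beta1 a* + beta2'c))

    OR_NIE = (1 + exp(beta0 + beta1 a* + beta2'c))
             * (1 + exp(beta0 + beta1 a  + beta2'c + theta2 + theta3 a))
             / ((1 + exp(beta0 + beta1 a  + beta2'c))
                * (1 + exp(beta0 + beta1 a* + beta2'c + theta2 + theta3 a)))

    OR_TE  = OR_NDE * OR_NIE            (an identity, not an estimate)

With the exposure-mediator interaction off, theta3 = 0 throughout and the
product decomposition of the classic difference/product methods is
recovered. The proportion mediated is log(OR_NIE)/log(OR_TE).

The conditional odds ratios depend on covariates only through the
mediator-model contribution beta2'c; by default c is the weighted mean of
the indicator-coded covariate columns in the analysis sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import glm
from .cohort import AGE_LEVELS, EDU_LEVELS
from .design import SurveyDesign
from .errors import (ConvergenceWarning, EstimationError, InputError,
                     UndefinedProportionWarning)
from .glm import INTERCEPT, LogisticFit, ModelSpec, Term

DEFAULT_COVARIATES: tuple[Term, ...] = (
    Term("age_group", AGE_LEVELS),
    Term("education", EDU_LEVELS),
)


@dataclass(frozen=True)
class MediationSpec:
    """Declaration of one mediation analysis cell.

    ``covariate_evaluation`` selects the covariate setting c at which the
    conditional odds ratios are reported: ``"weighted_mean"`` (default, the
    weighted mean of the indicator-coded covariate columns), ``"modal"``
    (the weighted-modal level of each covariate) or an explicit mapping of
    covariate name to level.
    """

    exposure: str
    mediator: str
    outcome: str
    covariates: tuple[Term, ...] = DEFAULT_COVARIATES
    include_interaction: bool = True
    covariate_evaluation: str | Mapping[str, str] = "weighted_mean"

    def __post_init__(self) -> None:
        if self.mediator == self.outcome:
            raise InputError("mediator and outcome must differ")
        if self.exposure in (self.mediator, self.outcome):
            raise InputError("exposure must differ from mediator and outcome")
        if isinstance(self.covariate_evaluation, str):
            if self.covariate_evaluation not in ("weighted_mean", "modal"):
                raise InputError(
                    "covariate_evaluation must be 'weighted_mean', 'modal' "
                    "or an explicit {covariate: level} mapping")

    @property
    def variables(self) -> list[str]:
        return ([self.exposure, self.mediator, self.outcome]
                + [t.name for t in self.covariates])


@dataclass
class MediationEstimate:
    """Point estimates (and, once bootstrapped, percentile CIs).

    ``or_te == or_nde * or_nie`` holds to machine precision by construction.
    ``pm`` is NaN with ``pm_defined=False`` when the total-effect OR is 1.
    """

    or_te: float
    or_nde: float
    or_nie: float
    pm: float
    pm_defined: bool
    n_used: int
    ci_te: tuple[float, float] | None = None
    ci_nde: tuple[float, float] | None = None
    ci_nie: tuple[float, float] | None = None
    ci_pm: tuple[float, float] | None = None
    n_bootstrap_ok: int | None = None
    meta: dict = field(default_factory=dict)


def _covariate_linpred(fit: LogisticFit, c_setting: Mapping[str, float],
                       covariates: Sequence[Term]) -> float:
    total = 0.0
    for term in covariates:
        for col in term.column_names:
            if col not in c_setting:
                raise InputError(f"covariate setting is missing {col!r}")
            total += float(fit.coefficients[col]) * float(c_setting[col])
    return total


def combine_effects(outcome_fit: LogisticFit, mediator_fit: LogisticFit,
                    spec: MediationSpec,
                    c_setting: Mapping[str, float]
                    ) -> tuple[float, float, float]:
    """Combine the two fitted models into (OR_NDE, OR_NIE, OR_TE).

    ``c_setting`` maps each indicator-coded covariate column (e.g.
    ``age_group[26-35]``) to its value at the evaluation point; fractional
    values encode a covariate mean.
    """
    coef_o = outcome_fit.coefficients
    coef_m = mediator_fit.coefficients
    th1 = float(coef_o[spec.exposure])
    th2 = float(coef_o[spec.mediator])
    inter_name = f"{spec.exposure}:{spec.mediator}"
    th3 = float(coef_o[inter_name]) if spec.include_interaction else 0.0
    b0 = float(coef_m[INTERCEPT])
    b1 = float(coef_m[spec.exposure])
    bc = _covariate_linpred(mediator_fit, c_setting, spec.covariates)
    values = (th1, th2, th3, b0, b1, bc)
    if not all(math.isfinite(v) for v in values):
        raise EstimationError(
            f"non-finite coefficient in mediation combination: {values}")
    k = b0 + bc  # mediator linear predictor at a*=0 and setting c
    or_nde = (math.exp(th1) * (1.0 + math.exp(th2 + th3 + k))
              / (1.0 + math.exp(th2 + k)))
    or_nie = ((1.0 + math.exp(k)) * (1.0 + math.exp(k + b1 + th2 + th3))
              / ((1.0 + math.exp(k + b1))
                 * (1.0 + math.exp(k + th2 + th3))))
    return or_nde, or_nie, or_nde * or_nie


def proportion_mediated(or_nie: float, or_te: float) -> float:
    """Proportion mediated on the log odds-ratio scale.

    Returns ``log(or_nie) / log(or_te)``; NaN (with a warning) when the
    total-effect OR equals 1, and values outside [0, 1] as-is with a warning
    when direct and indirect effects point in opposite directions.
    """
    if or_nie <= 0.0 or or_te <= 0.0:
        raise InputError("odds ratios must be strictly positive")
    log_te = math.log(or_te)
    if abs(log_te) < 1e-12:
        warnings.warn("proportion mediated undefined: total-effect OR is 1",
                      UndefinedProportionWarning, stacklevel=2)
        return float("nan")
    pm = math.log(or_nie) / log_te
    if not 0.0 <= pm <= 1.0:
        warnings.warn(
            f"proportion mediated {pm:.3f} outside [0, 1]: direct and "
            "indirect effects point in opposite directions",
            UndefinedProportionWarning, stacklevel=2)
    return pm


# --------------------------------------------------------------------------
# prepared problem: one listwise deletion + design-matrix build, reused by
# the point estimate and every bootstrap replicate


class MediationProblem:
    """A mediation analysis cell frozen into numpy arrays.

    Built once per cell: listwise deletion over all modelling variables,
    both design matrices, weights and design labels. ``estimate`` then works
    on row-index subsets, which is what makes cluster-bootstrap replicates
    cheap.
    """

    def __init__(self, cohort: pd.DataFrame, spec: MediationSpec,
                 design: SurveyDesign):
        design.validate(cohort)
        needed = spec.variables + design.columns()
        missing_cols = [c for c in needed if c not in cohort.columns]
        if missing_cols:
            raise InputError(f"columns missing from cohort: {missing_cols}")
        data = cohort.dropna(subset=spec.variables).reset_index(drop=True)
        if len(data) == 0:
            raise EstimationError("no complete cases for mediation cell")
        self.spec = spec
        self.design = design
        self.data = data
        self.n_used = len(data)

        med_terms = (Term(spec.exposure),) + spec.covariates
        out_terms = (Term(spec.exposure), Term(spec.mediator)) + spec.covariates
        interaction = ((spec.exposure, spec.mediator)
                       if spec.include_interaction else None)
        self.mediator_spec = ModelSpec(spec.mediator, med_terms,
                                       weight=design.weight)
        self.outcome_spec = ModelSpec(spec.outcome, out_terms,
                                      interaction=interaction,
                                      weight=design.weight)
        self.Xm, self.names_m = glm.build_design(data, med_terms)
        self.Xo, self.names_o = glm.build_design(data, out_terms, interaction)
        self.ym = data[spec.mediator].to_numpy(dtype=float)
        self.yo = data[spec.outcome].to_numpy(dtype=float)
        self.a = data[spec.exposure].to_numpy(dtype=float)
        self.w = data[design.weight].to_numpy(dtype=float)
        for name, y in ((spec.mediator, self.ym), (spec.outcome, self.yo),
                        (spec.exposure, self.a)):
            if not np.isin(y, (0.0, 1.0)).all():
                raise InputError(f"column {name!r} must be binary 0/1")
        self.strata = data[design.stratum].to_numpy()
        self.psus = data[design.psu].to_numpy()
        # indicator columns of the covariates within the mediator design
        self.cov_cols = [c for t in spec.covariates for c in t.column_names]
        self.cov_idx = np.array([self.names_m.index(c)
                                 for c in self.cov_cols], dtype=int)
        self._fixed_c = self._fixed_covariate_setting()

    def _fixed_covariate_setting(self) -> dict[str, float] | None:
        """Covariate setting for 'modal' / explicit evaluation; None for the
        per-sample weighted mean (recomputed on each replicate)."""
        ev = self.spec.covariate_evaluation
        if ev == "weighted_mean":
            return None
        setting: dict[str, float] = {}
        if ev == "modal":
            for term in self.spec.covariates:
                series = self.data[term.name].astype(object)
                totals = pd.Series(self.w).groupby(series.to_numpy()).sum()
                modal = totals.idxmax()
                for lev in term.levels[1:]:  # type: ignore[union-attr]
                    setting[f"{term.name}[{lev}]"] = float(lev == modal)
            return setting
        for term in self.spec.covariates:
            if term.name not in ev:  # type: ignore[operator]
                raise InputError(
                    f"explicit covariate setting is missing {term.name!r}")
            value = ev[term.name]  # type: ignore[index]
            if term.levels is None:
                setting[term.name] = float(value)  # type: ignore[arg-type]
            else:
                if value not in term.levels:
                    raise InputError(
                        f"{value!r} is not a level of {term.name!r}")
                for lev in term.levels[1:]:
                    setting[f"{term.name}[{lev}]"] = float(lev == value)
        return setting

    def covariate_setting(self, idx: np.ndarray | None) -> dict[str, float]:
        if self._fixed_c is not None:
            return self._fixed_c
        if idx is None:
            X, w = self.Xm, self.w
        else:
            X, w = self.Xm[idx], self.w[idx]
        means = (X[:, self.cov_idx] * w[:, None]).sum(axis=0) / w.sum()
        return dict(zip(self.cov_cols, means.tolist()))

    def _check_rows(self, idx: np.ndarray | None) -> tuple:
        if idx is None:
            return self.Xm, self.ym, self.Xo, self.yo, self.a, self.w
        return (self.Xm[idx], self.ym[idx], self.Xo[idx], self.yo[idx],
                self.a[idx], self.w[idx])

    def estimate(self, idx: np.ndarray | None = None,
                 start_m: np.ndarray | None = None,
                 start_o: np.ndarray | None = None,
                 strict_separation: bool = True
                 ) -> tuple[MediationEstimate, np.ndarray, np.ndarray]:
        """Fit both models on the rows ``idx`` (all rows when None) and
        combine. Returns the estimate plus both coefficient vectors (used as
        warm starts for bootstrap replicates).

        Raises :class:`EstimationError` on degenerate subsets (a constant
        exposure, mediator or outcome), non-convergence, or — when
        ``strict_separation`` — detected separation.
        """
        Xm, ym, Xo, yo, a, w = self._check_rows(idx)
        for label, v in (("exposure", a), ("mediator", ym), ("outcome", yo)):
            if v.min() == v.max():
                raise EstimationError(f"{label} class empty in subset")
        beta_m, conv_m, sep_m = glm.irls(Xm, ym, w, beta0=start_m)
        beta_o, conv_o, sep_o = glm.irls(Xo, yo, w, beta0=start_o)
        if not (conv_m and conv_o):
            raise EstimationError("logistic fit did not converge")
        if strict_separation and (sep_m or sep_o):
            raise EstimationError("separation detected in logistic fit")
        fit_m = LogisticFit(pd.Series(beta_m, index=self.names_m), conv_m,
                            len(ym), sep_m, self.mediator_spec)
        fit_o = LogisticFit(pd.Series(beta_o, index=self.names_o), conv_o,
                            len(yo), sep_o, self.outcome_spec)
        c_setting = self.covariate_setting(idx)
        nde, nie, te = combine_effects(fit_o, fit_m, self.spec, c_setting)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedProportionWarning)
            pm = proportion_mediated(nie, te)
        est = MediationEstimate(
            or_te=te, or_nde=nde, or_nie=nie, pm=pm,
            pm_defined=math.isfinite(pm), n_used=len(ym),
            meta={
                "outcome_prevalence": float(np.average(yo, weights=w)),
                "include_interaction": self.spec.include_interaction,
                "covariate_evaluation": (
                    self.spec.covariate_evaluation
                    if isinstance(self.spec.covariate_evaluation, str)
                    else dict(self.spec.covariate_evaluation)),
            })
        return est, beta_m, beta_o


def run_mediation(cohort: pd.DataFrame, spec: MediationSpec,
                  design: SurveyDesign) -> MediationEstimate:
    """Point estimation for one mediation cell (no confidence intervals).

    The cohort is expected to be sex-filtered already; listwise deletion over
    exposure, mediator, outcome and covariates is applied here. Separation
    in either model is an error on this path (bootstrap replicates instead
    drop silently).
    """
    problem = MediationProblem(cohort, spec, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est, _, _ = problem.estimate(strict_separation=True)
    if not est.pm_defined:
        warnings.warn("proportion mediated undefined: total-effect OR is 1",
                      UndefinedProportionWarning, stacklevel=2)
    return est


def fits_from_structural(params, exposure: str = "sae_lifetime"
                         ) -> tuple[LogisticFit, LogisticFit]:
    """Package a :class:`~survmediate.cohort.StructuralParams` as a pair of
    (outcome_fit, mediator_fit) coefficient vectors.

    Lets :func:`combine_effects` be evaluated at the *true* generator
    coefficients, isolating the rare-outcome approximation of the OR
    formulas from sampling error.
    """
    cov_terms = DEFAULT_COVARIATES

    def as_fit(model, response: str, with_mediator: bool) -> LogisticFit:
        names = [INTERCEPT, exposure]
        values = [model.intercept, model.exposure]
        terms: list[Term] = [Term(exposure)]
        if with_mediator:
            names.append(params.mediator_name)
            values.append(model.mediator)
            terms.append(Term(params.mediator_name))
        for term, coefs in zip(cov_terms, (model.age, model.education)):
            terms.append(term)
            for lev, coef in zip(term.levels[1:], coefs[1:]):  # type: ignore[union-attr]
                names.append(f"{term.name}[{lev}]")
                values.append(coef)
        interaction = None
        if with_mediator:
            names.append(f"{exposure}:{params.mediator_name}")
            values.append(model.interaction)
            interaction = (exposure, params.mediator_name)
        spec = ModelSpec(response, tuple(terms), interaction=interaction)
        return LogisticFit(pd.Series(values, index=names, dtype=float),
                           converged=True, n_used=0,
                           separation_detected=False, spec=spec)

    outcome_fit = as_fit(params.outcome_model, params.outcome_name, True)
    mediator_fit = as_fit(params.mediator_model, params.mediator_name, False)
    return outcome_fit, mediator_fit


def structural_covariate_setting(params, c_value="modal") -> dict[str, float]:
    """Indicator-coded covariate setting matching the oracle's ``c_value``."""
    setting: dict[str, float] = {}
    if c_value == "modal":
        age = AGE_LEVELS[int(np.argmax(params.age_probs))]
        edu = EDU_LEVELS[int(np.argmax(params.edu_probs))]
        for lev in AGE_LEVELS[1:]:
            setting[f"age_group[{lev}]"] = float(lev == age)
        for lev in EDU_LEVELS[1:]:
            setting[f"education[{lev}]"] = float(lev == edu)
        return setting
    if c_value == "weighted_mean":
        for lev, p in zip(AGE_LEVELS[1:], params.age_probs[1:]):
            setting[f"age_group[{lev}]"] = float(p)
        for lev, p in zip(EDU_LEVELS[1:], params.edu_probs[1:]):
            setting[f"education[{lev}]"] = float(p)
        return setting
    if isinstance(c_value, tuple) and len(c_value) == 2:
        age, edu = c_value
        for lev in AGE_LEVELS[1:]:
            setting[f"age_group[{lev}]"] = float(lev == age)
        for lev in EDU_LEVELS[1:]:
            setting[f"education[{lev}]"] = float(lev == edu)
        return setting
    raise InputError(f"unsupported covariate setting {c_value!r}")
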