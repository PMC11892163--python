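"""Synthetic survey-cohort simulator with known true mediation effects.

The study data this package is designed to analyse — a nationally
representative sexual-health survey with a stratified-cluster design — is not
publicly deposited, so this module generates cohorts with the same structure:

* covariates: sex (cohorts are generated per sex), six age groups, three
  education levels drawn from the published marginal distributions;
* a binary exposure (lifetime sexual-assault experience, SAE) with nested
  childhood and repeated-event flags;
* one binary mediator and one binary outcome (hazardous alcohol use, heavy
  tobacco use, frequent cannabis use, depression treatment) generated from
  logistic structural equations following the assumed causal graph
  covariates -> exposure -> mediator -> outcome;
* a generic stratified-cluster design with log-normal weights, and optional
  missing-completely-at-random missingness.

Model intercepts are calibrated by exact enumeration over the finite
covariate support so that every marginal prevalence matches its published
target; because the calibration is exact, simulated prevalences deviate from
the targets only by Monte-Carlo noise.

Because both the mediator and the outcome are binary, every counterfactual
quantity is a finite sum, and :func:`oracle_true_effects` returns the exact
conditional odds ratios (natural direct, natural indirect and total effect)
implied by the structural parameters — the ground truth that recovery and
coverage tests measure estimators against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import InputError

AGE_LEVELS: tuple[str, ...] = (
    "18-25", "26-35", "36-45", "46-55", "56-65", "66-75")
EDU_LEVELS: tuple[str, ...] = ("high", "medium", "low")
SUBSTANCES: tuple[str, ...] = (
    "hazardous_alcohol", "heavy_tobacco", "frequent_cannabis")
DEPRESSION = "depression"
VARIABLES: tuple[str, ...] = SUBSTANCES + (DEPRESSION,)

EXPOSURE = "sae_lifetime"
CHILDHOOD = "sae_childhood"
REPEATED = "sae_repeated"
RECENT = "sae_recent"

#: Published weighted prevalences (proportions) used as calibration targets.
PUBLISHED_PREVALENCE: dict[str, dict[str, float]] = {
    "female": {
        EXPOSURE: 0.140, CHILDHOOD: 0.031,
        "hazardous_alcohol": 0.007, "heavy_tobacco": 0.078,
        "frequent_cannabis": 0.010, DEPRESSION: 0.107,
    },
    "male": {
        EXPOSURE: 0.027, CHILDHOOD: 0.008,
        "hazardous_alcohol": 0.009, "heavy_tobacco": 0.123,
        "frequent_cannabis": 0.026, DEPRESSION: 0.056,
    },
}


def _normalised(values: tuple[float, ...]) -> tuple[float, ...]:
    total = float(sum(values))
    return tuple(v / total for v in values)


#: Published age-group and education marginals per sex (weighted %).
AGE_PROBS: dict[str, tuple[float, ...]] = {
    "female": _normalised((11.5, 17.1, 16.4, 21.3, 19.2, 14.3)),
    "male": _normalised((12.5, 18.0, 16.2, 21.8, 18.7, 12.6)),
}
EDU_PROBS: dict[str, tuple[float, ...]] = {
    "female": _normalised((36.5, 35.2, 28.1)),
    "male": _normalised((36.6, 28.9, 34.4)),
}

#: Default per-column missingness rates, from the published missing counts
#: (e.g. hazardous alcohol 119/2563 among women). The childhood-SAE rate is
#: capped at 4.9% to honour the <5% default bound.
DEFAULT_MISSING_RATES: dict[str, dict[str, float]] = {
    "female": {
        EXPOSURE: 0.013, CHILDHOOD: 0.049,
        "hazardous_alcohol": 0.046, "heavy_tobacco": 0.003,
        "frequent_cannabis": 0.002, DEPRESSION: 0.0,
    },
    "male": {
        EXPOSURE: 0.013, CHILDHOOD: 0.020,
        "hazardous_alcohol": 0.031, "heavy_tobacco": 0.004,
        "frequent_cannabis": 0.002, DEPRESSION: 0.0,
    },
}

# Default structural effect sizes (log odds ratios). Chosen once to land the
# simulated total/indirect effects in the range of the published mediation
# tables; the study's latent coefficients are unknown.
DEFAULT_EXPOSURE_TO_MEDIATOR = math.log(2.0)
DEFAULT_EXPOSURE_TO_OUTCOME = math.log(3.0)
DEFAULT_MEDIATOR_TO_OUTCOME = math.log(2.5)

# Mild covariate gradients on the logit scale (reference level first).
_AGE_TREND: tuple[float, ...] = (0.0, 0.20, 0.25, 0.20, 0.10, 0.0)
_EDU_TREND: tuple[float, ...] = (0.0, 0.10, 0.20)


@dataclass(frozen=True)
class LogitModel:
    """Linear predictor of one structural equation on the logit scale.

    ``age`` and ``education`` hold one additive contribution per level, with
    the first (reference) level fixed at 0 by convention.
    """

    intercept: float
    age: tuple[float, ...] = (0.0,) * 6
    education: tuple[float, ...] = (0.0,) * 3
    exposure: float = 0.0
    mediator: float = 0.0
    interaction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.age) != len(AGE_LEVELS):
            raise InputError("age coefficients must have 6 entries")
        if len(self.education) != len(EDU_LEVELS):
            raise InputError("education coefficients must have 3 entries")

    def linpred(self, age_idx: np.ndarray, edu_idx: np.ndarray,
                a: np.ndarray | float = 0.0,
                m: np.ndarray | float = 0.0) -> np.ndarray:
        age = np.asarray(self.age)[age_idx]
        edu = np.asarray(self.education)[edu_idx]
        return (self.intercept + age + edu + self.exposure * np.asarray(a)
                + self.mediator * np.asarray(m)
                + self.interaction * np.asarray(a) * np.asarray(m))


@dataclass(frozen=True)
class StructuralParams:
    """Complete description of one synthetic cohort's data-generating process."""

    sex: str
    age_probs: tuple[float, ...]
    edu_probs: tuple[float, ...]
    exposure_model: LogitModel
    mediator_model: LogitModel
    outcome_model: LogitModel
    mediator_name: str
    outcome_name: str
    childhood_given_lifetime: float
    repeated_given_lifetime: float = 0.45
    recent_rate: float = 0.005
    n_strata: int = 10
    psus_per_stratum: int = 20
    weight_sigma: float = 0.5
    missing_rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, probs, k in (("age_probs", self.age_probs, 6),
                               ("edu_probs", self.edu_probs, 3)):
            if len(probs) != k or abs(sum(probs) - 1.0) > 1e-9:
                raise InputError(f"{name} must be a length-{k} probability "
                                 "vector summing to 1")
            if any(p < 0 for p in probs):
                raise InputError(f"{name} entries must be non-negative")
        for name, p in (("childhood_given_lifetime",
                         self.childhood_given_lifetime),
                        ("repeated_given_lifetime",
                         self.repeated_given_lifetime),
                        ("recent_rate", self.recent_rate)):
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{name} must be in [0, 1]")
        if self.n_strata < 1 or self.psus_per_stratum < 1:
            raise InputError("design must have >= 1 stratum and PSU")
        if self.weight_sigma < 0:
            raise InputError("weight_sigma must be non-negative")
        for col, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise InputError(f"missing rate for {col!r} outside [0, 1]")
        if self.mediator_name == self.outcome_name:
            raise InputError("mediator and outcome must differ")


@dataclass(frozen=True)
class TruthRecord:
    """Exact counterfactual effects implied by a parameter set.

    ``true_or_te == true_or_nde * true_or_nie`` holds exactly by
    construction (the three odds ratios share intermediate odds).
    ``pm_defined`` is False when the total effect is null, in which case
    ``true_pm`` is NaN.
    """

    covariate_setting: str
    true_or_nde: float
    true_or_nie: float
    true_or_te: float
    true_pm: float
    pm_defined: bool


# --------------------------------------------------------------------------
# calibration


def _covariate_cells(params_or_probs) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
    """Flattened (age, edu) support with cell probabilities."""
    if isinstance(params_or_probs, StructuralParams):
        age_probs = np.asarray(params_or_probs.age_probs)
        edu_probs = np.asarray(params_or_probs.edu_probs)
    else:
        age_probs, edu_probs = map(np.asarray, params_or_probs)
    age_idx, edu_idx = np.meshgrid(np.arange(len(age_probs)),
                                   np.arange(len(edu_probs)), indexing="ij")
    p_cell = np.outer(age_probs, edu_probs)
    return age_idx.ravel(), edu_idx.ravel(), p_cell.ravel()


def _solve_intercept(marginal, target: float) -> float:
    """Root of ``marginal(b0) == target`` over a wide logit bracket."""
    return float(brentq(lambda b0: marginal(b0) - target, -30.0, 15.0,
                        xtol=1e-12))


def expected_mediator_prevalence(params: StructuralParams) -> float:
    """Closed-form marginal P(mediator=1) over the finite covariate support."""
    age_idx, edu_idx, p_cell = _covariate_cells(params)
    p_a = expit(params.exposure_model.linpred(age_idx, edu_idx))
    out = 0.0
    for a in (0.0, 1.0):
        pa = p_a if a == 1.0 else 1.0 - p_a
        out += float(np.sum(
            p_cell * pa * expit(params.mediator_model.linpred(
                age_idx, edu_idx, a=a))))
    return out


def expected_outcome_prevalence(params: StructuralParams) -> float:
    """Closed-form marginal P(outcome=1) over covariates, exposure, mediator."""
    age_idx, edu_idx, p_cell = _covariate_cells(params)
    p_a = expit(params.exposure_model.linpred(age_idx, edu_idx))
    out = 0.0
    for a in (0.0, 1.0):
        pa = p_a if a == 1.0 else 1.0 - p_a
        p_m = expit(params.mediator_model.linpred(age_idx, edu_idx, a=a))
        for m in (0.0, 1.0):
            pm = p_m if m == 1.0 else 1.0 - p_m
            out += float(np.sum(
                p_cell * pa * pm * expit(params.outcome_model.linpred(
                    age_idx, edu_idx, a=a, m=m))))
    return out


def default_params(sex: str,
                   mediator: str = "heavy_tobacco",
                   outcome: str = DEPRESSION,
                   exposure_to_mediator: float = DEFAULT_EXPOSURE_TO_MEDIATOR,
                   exposure_to_outcome: float = DEFAULT_EXPOSURE_TO_OUTCOME,
                   mediator_to_outcome: float = DEFAULT_MEDIATOR_TO_OUTCOME,
                   interaction: float = 0.0) -> StructuralParams:
    """Structural parameters calibrated to the published marginal prevalences.

    The returned intercepts are solved so that the exact marginal prevalence
    of the exposure, the chosen mediator and the chosen outcome equal their
    published sex-specific targets; childhood SAE is nested within lifetime
    SAE at the published ratio.

    Parameters
    ----------
    sex
        ``"female"`` or ``"male"``; selects the target prevalences and the
        covariate marginals.
    mediator, outcome
        Which of the four binary health variables play the mediator and
        outcome roles in this cohort (they must differ).
    exposure_to_mediator, exposure_to_outcome, mediator_to_outcome, interaction
        Structural log odds ratios; defaults give effect sizes in the range
        of the published mediation tables.
    """
    if sex not in PUBLISHED_PREVALENCE:
        raise InputError(f"unknown sex label {sex!r}; "
                         "expected 'female' or 'male'")
    if mediator not in VARIABLES:
        raise InputError(f"unknown mediator {mediator!r}")
    if outcome not in VARIABLES:
        raise InputError(f"unknown outcome {outcome!r}")
    if mediator == outcome:
        raise InputError("mediator and outcome must differ")
    targets = PUBLISHED_PREVALENCE[sex]
    age_probs, edu_probs = AGE_PROBS[sex], EDU_PROBS[sex]
    age_idx, edu_idx, p_cell = _covariate_cells((age_probs, edu_probs))
    age_arr = np.asarray(_AGE_TREND)[age_idx]
    edu_arr = np.asarray(_EDU_TREND)[edu_idx]

    b0_exposure = _solve_intercept(
        lambda b0: float(np.sum(p_cell * expit(b0 + age_arr + edu_arr))),
        targets[EXPOSURE])
    exposure_model = LogitModel(intercept=b0_exposure, age=_AGE_TREND,
                                education=_EDU_TREND)

    def make(intercept: float, model_kind: str) -> StructuralParams:
        med = LogitModel(intercept=intercept if model_kind == "m" else 0.0,
                         age=_AGE_TREND, education=_EDU_TREND,
                         exposure=exposure_to_mediator)
        out = LogitModel(intercept=intercept if model_kind == "y" else 0.0,
                         age=_AGE_TREND, education=_EDU_TREND,
                         exposure=exposure_to_outcome,
                         mediator=mediator_to_outcome,
                         interaction=interaction)
        return StructuralParams(
            sex=sex, age_probs=age_probs, edu_probs=edu_probs,
            exposure_model=exposure_model, mediator_model=med,
            outcome_model=out, mediator_name=mediator, outcome_name=outcome,
            childhood_given_lifetime=targets[CHILDHOOD] / targets[EXPOSURE],
            missing_rates={col: DEFAULT_MISSING_RATES[sex][col]
                           for col in (EXPOSURE, CHILDHOOD, mediator,
                                       outcome)})

    b0_mediator = _solve_intercept(
        lambda b0: expected_mediator_prevalence(make(b0, "m")),
        targets[mediator])
    partial = make(b0_mediator, "m")

    def outcome_marginal(b0: float) -> float:
        return expected_outcome_prevalence(replace(
            partial,
            outcome_model=replace(partial.outcome_model, intercept=b0)))

    b0_outcome = _solve_intercept(outcome_marginal, targets[outcome])
    return replace(partial, outcome_model=replace(partial.outcome_model,
                                                  intercept=b0_outcome))


# --------------------------------------------------------------------------
# generation


def generate_cohort(params: StructuralParams, n: int, seed: int
                    ) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw a complete cohort of ``n`` records; deterministic given ``seed``.

    Records are independent given the design: stratum/PSU labels and
    log-normal weights are drawn independently of the substantive variables
    (the design exists to exercise design-based code paths), covariates come
    from their categorical marginals, and exposure, mediator and outcome are
    drawn sequentially from the logistic structural equations. The returned
    :class:`TruthRecord` holds the exact effects at the modal covariate cell.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InputError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    stratum = rng.integers(0, params.n_strata, size=n)
    psu = stratum * params.psus_per_stratum + rng.integers(
        0, params.psus_per_stratum, size=n)
    weight = rng.lognormal(mean=-params.weight_sigma ** 2 / 2.0,
                           sigma=params.weight_sigma, size=n)
    weight = weight / weight.mean()

    # inverse-CDF categorical draws (much faster than Generator.choice)
    age_idx = np.searchsorted(np.cumsum(params.age_probs)[:-1],
                              rng.random(n), side="right")
    edu_idx = np.searchsorted(np.cumsum(params.edu_probs)[:-1],
                              rng.random(n), side="right")

    a = (rng.random(n) < expit(
        params.exposure_model.linpred(age_idx, edu_idx))).astype(float)
    childhood = a * (rng.random(n)
                     < params.childhood_given_lifetime).astype(float)
    repeated = a * (rng.random(n)
                    < params.repeated_given_lifetime).astype(float)
    recent = (rng.random(n) < params.recent_rate).astype(float)
    m = (rng.random(n) < expit(
        params.mediator_model.linpred(age_idx, edu_idx, a=a))).astype(float)
    y = (rng.random(n) < expit(
        params.outcome_model.linpred(age_idx, edu_idx, a=a, m=m))
         ).astype(float)

    table = pd.DataFrame({
        "sex": params.sex,
        "age_group": pd.Categorical.from_codes(age_idx,
                                               categories=AGE_LEVELS),
        "education": pd.Categorical.from_codes(edu_idx,
                                               categories=EDU_LEVELS),
        "weight": weight,
        "stratum": stratum,
        "psu": psu,
        EXPOSURE: a,
        CHILDHOOD: childhood,
        REPEATED: repeated,
        RECENT: recent,
        params.mediator_name: m,
        params.outcome_name: y,
    })
    return table, oracle_true_effects(params, "modal")


def inject_missingness(cohort: pd.DataFrame,
                       rates: Mapping[str, float],
                       seed: int) -> pd.DataFrame:
    """Blank cells completely at random, column by column.

    Each eligible cell of a column listed in ``rates`` is independently set
    to missing with that column's probability. Deterministic given ``seed``;
    the input frame is not modified.
    """
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for col in sorted(rates):
        rate = rates[col]
        if not 0.0 <= rate <= 1.0:
            raise InputError(f"missing rate for {col!r} outside [0, 1]")
        if col not in out.columns:
            raise InputError(f"column {col!r} not in cohort")
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        out[col] = out[col].astype(float).where(~mask)
    return out


# --------------------------------------------------------------------------
# exact counterfactual oracle


def _covariate_contribution(model: LogitModel, params: StructuralParams,
                            c_value) -> float:
    if c_value == "modal":
        i = int(np.argmax(params.age_probs))
        j = int(np.argmax(params.edu_probs))
        return model.age[i] + model.education[j]
    if c_value == "weighted_mean":
        return (float(np.dot(model.age, params.age_probs))
                + float(np.dot(model.education, params.edu_probs)))
    if isinstance(c_value, tuple) and len(c_value) == 2:
        age_level, edu_level = c_value
        if age_level not in AGE_LEVELS or edu_level not in EDU_LEVELS:
            raise InputError(f"unknown covariate levels {c_value!r}")
        return (model.age[AGE_LEVELS.index(age_level)]
                + model.education[EDU_LEVELS.index(edu_level)])
    raise InputError(
        "c_value must be 'modal', 'weighted_mean' or an "
        "(age_level, education_level) pair")


def oracle_true_effects(params: StructuralParams,
                        c_value="modal") -> TruthRecord:
    """Exact conditional natural-effect odds ratios at a covariate setting.

    With a binary mediator the counterfactual risk is a two-term sum,

    ``P(Y_{a, M_{a*}} = 1 | c) = sum_m P(Y=1 | a, m, c) P(M=m | a*, c)``,

    so no simulation is involved. The total effect compares (a=1, a*=1) to
    (a=0, a*=0), the natural direct effect (1, 0) to (0, 0) and the natural
    indirect effect (1, 1) to (1, 0); each is converted to an odds ratio.
    The proportion mediated is log(OR_NIE)/log(OR_TE), undefined (flagged)
    when the total effect is null.
    """
    cm = _covariate_contribution(params.mediator_model, params, c_value)
    cy = _covariate_contribution(params.outcome_model, params, c_value)
    med, out = params.mediator_model, params.outcome_model

    def p_mediator(a: float) -> float:
        return float(expit(med.intercept + med.exposure * a + cm))

    def risk(a: float, a_star: float) -> float:
        p1 = p_mediator(a_star)
        total = 0.0
        for m, pm in ((0.0, 1.0 - p1), (1.0, p1)):
            total += pm * float(expit(
                out.intercept + out.exposure * a + out.mediator * m
                + out.interaction * a * m + cy))
        return total

    def odds(a: float, a_star: float) -> float:
        r = risk(a, a_star)
        return r / (1.0 - r)

    o00, o10, o11 = odds(0, 0), odds(1, 0), odds(1, 1)
    or_nde = o10 / o00
    or_nie = o11 / o10
    or_te = o11 / o00
    log_te = math.log(or_te)
    pm_defined = abs(log_te) > 1e-12
    true_pm = math.log(or_nie) / log_te if pm_defined else float("nan")
    setting = c_value if isinstance(c_value, str) else f"{c_value}"
    return TruthRecord(covariate_setting=setting, true_or_nde=or_nde,
                       true_or_nie=or_nie, true_or_te=or_te,
                       true_pm=true_pm, pm_defined=pm_defined)


def simulate_counterfactual_effects(params: StructuralParams, c_value,
                                    n_draws: int, seed: int
                                    ) -> tuple[float, float, float]:
    """Brute-force Monte-Carlo counterfactual odds ratios at a fixed
    covariate setting; the simulation cross-check for the closed-form oracle.
    """
    cm = _covariate_contribution(params.mediator_model, params, c_value)
    cy = _covariate_contribution(params.outcome_model, params, c_value)
    med, out = params.mediator_model, params.outcome_model
    rng = np.random.default_rng(seed)

    def risk_hat(a: float, a_star: float) -> float:
        m = (rng.random(n_draws)
             < expit(med.intercept + med.exposure * a_star + cm))
        y = rng.random(n_draws) < expit(
            out.intercept + out.exposure * a + out.mediator * m
            + out.interaction * a * m + cy)
        return float(y.mean())

    def odds_hat(a: float, a_star: float) -> float:
        r = risk_hat(a, a_star)
        return r / (1.0 - r)

    o00, o10, o11 = odds_hat(0, 0), odds_hat(1, 0), odds_hat(1, 1)
    return o10 / o00, o11 / o10, o11 / o00


# --------------------------------------------------------------------------
# persistence


def write_cohort(table: pd.DataFrame, path: str | Path,
                 params: StructuralParams | None = None,
                 truth: TruthRecord | None = None) -> None:
    """Write a cohort as CSV; parameters and truth go to a JSON sidecar."""
    path = Path(path)
    table.to_csv(path, index=False)
    if params is None and truth is None:
        return
    sidecar: dict = {}
    if params is not None:
        sidecar["params"] = asdict(params)
    if truth is not None:
        sidecar["truth"] = asdict(truth)
    path.with_suffix(".params.json").write_text(
        json.dumps(sidecar, indent=2, default=list))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, restoring the categorical covariate columns."""
    table = pd.read_csv(path)
    for col, levels in (("age_group", AGE_LEVELS), ("education", EDU_LEVELS)):
        if col in table.columns:
            table[col] = pd.Categorical(table[col], categories=levels)
    return table
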