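"""Design-based prevalence estimation and the respondent exclusion flow.

Prevalences are weighted ratio estimates with Taylor-linearised variances
over strata and primary sampling units; 95% intervals are formed on the
logit scale and back-transformed, the convention of mainstream survey
software. Group comparisons use the conservative rule of flagging a
difference only when two 95% intervals are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .design import SurveyDesign
from .errors import EstimationError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A weighted prevalence with its design-based confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    n_unweighted: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise InputError("CI endpoints must bracket the point in [0, 1]")
        if self.n_unweighted < 1:
            raise InputError("n_unweighted must be >= 1")


def _linearised_variance(x: np.ndarray, w: np.ndarray, strata: np.ndarray,
                         psus: np.ndarray, point: float) -> float:
    """Taylor-linearised variance of the ratio estimator sum(w x)/sum(w)."""
    total_w = w.sum()
    z = w * (x - point) / total_w
    frame = pd.DataFrame({"z": z, "stratum": strata, "psu": psus})
    per_psu = frame.groupby(["stratum", "psu"], observed=True)["z"].sum()
    variance = 0.0
    for _, zh in per_psu.groupby(level="stratum", observed=True):
        n_h = len(zh)
        if n_h < 2:
            logger.debug("single-PSU stratum contributes no variance")
            continue
        variance += n_h / (n_h - 1) * float(((zh - zh.mean()) ** 2).sum())
    return variance


def weighted_prevalence(cohort: pd.DataFrame, variable: str,
                        design: SurveyDesign,
                        level: float = 0.95) -> PrevalenceEstimate:
    """Design-based prevalence of a binary ``variable``.

    Records missing the variable are excluded first; the point estimate is
    the weighted proportion over the remaining records and the interval is a
    logit-scale Wald interval using the linearised design variance.

    Raises
    ------
    EstimationError
        If no record has a valid value for ``variable``.
    """
    if variable not in cohort.columns:
        raise InputError(f"variable {variable!r} not in cohort")
    design.validate(cohort)
    valid = cohort.dropna(subset=[variable])
    if len(valid) == 0:
        raise EstimationError(f"no valid records for {variable!r}")
    x = valid[variable].to_numpy(dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise InputError(f"variable {variable!r} must be binary 0/1")
    w = valid[design.weight].to_numpy(dtype=float)
    point = float(np.sum(w * x) / np.sum(w))
    if point in (0.0, 1.0):
        # all-constant variable: degenerate interval equal to the point
        return PrevalenceEstimate(point, point, point, len(valid))
    variance = _linearised_variance(
        x, w, valid[design.stratum].to_numpy(),
        valid[design.psu].to_numpy(), point)
    if variance <= 0.0:
        return PrevalenceEstimate(point, point, point, len(valid))
    z = norm.ppf(0.5 + level / 2.0)
    se_logit = float(np.sqrt(variance)) / (point * (1.0 - point))
    lo = float(expit(logit(point) - z * se_logit))
    hi = float(expit(logit(point) + z * se_logit))
    return PrevalenceEstimate(point, lo, hi, len(valid))


def ci_overlap_flag(a: PrevalenceEstimate, b: PrevalenceEstimate) -> bool:
    """True iff the two confidence intervals are disjoint.

    A shared endpoint counts as overlap (returns False) — the conservative
    tie-break.
    """
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low


@dataclass(frozen=True)
class ExclusionReport:
    """Counts removed by each exclusion rule, in the order applied."""

    n_input: int
    n_missing_exposure: int
    n_recent_exposure: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_missing_exposure - self.n_recent_exposure


def apply_exclusion_flow(raw: pd.DataFrame, exposure: str = "sae_lifetime",
                         recent: str = "sae_recent"
                         ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove records without exposure information, then recent-exposure
    records, reporting the count removed by each rule."""
    for col in (exposure, recent):
        if col not in raw.columns:
            raise InputError(f"exclusion flow needs column {col!r}")
    has_exposure = raw[exposure].notna()
    step1 = raw[has_exposure]
    not_recent = step1[recent].fillna(0).astype(float) != 1.0
    step2 = step1[not_recent]
    report = ExclusionReport(
        n_input=len(raw),
        n_missing_exposure=int((~has_exposure).sum()),
        n_recent_exposure=int((~not_recent).sum()),
    )
    return step2, report


def prevalence_table(cohort: pd.DataFrame, variables: dict[str, list | None],
                     design: SurveyDesign) -> pd.DataFrame:
    """Descriptive table: one row per variable (binary) or level (categorical).

    ``variables`` maps a column name to None (binary 0/1 column) or to its
    list of categorical levels, each reported as an indicator prevalence.
    Columns: variable, level, percent, ci_low, ci_high, n_unweighted (count
    of records in the level, matching the published table's convention),
    n_missing.
    """
    rows = []
    for var, levels in variables.items():
        n_missing = int(cohort[var].isna().sum())
        if levels is None:
            est = weighted_prevalence(cohort, var, design)
            n_level = int((cohort[var] == 1).sum())
            rows.append((var, "yes", 100 * est.point, 100 * est.ci_low,
                         100 * est.ci_high, n_level, n_missing))
        else:
            for lev in levels:
                work = cohort.copy()
                indicator = (work[var].astype(object) == lev).astype(float)
                indicator[work[var].isna()] = np.nan
                work["_indicator"] = indicator
                est = weighted_prevalence(work, "_indicator", design)
                rows.append((var, lev, 100 * est.point, 100 * est.ci_low,
                             100 * est.ci_high, int((indicator == 1).sum()),
                             n_missing))
    return pd.DataFrame(rows, columns=[
        "variable", "level", "percent", "ci_low", "ci_high",
        "n_unweighted", "n_missing"])
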