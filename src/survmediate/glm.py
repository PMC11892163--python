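"""Weighted logistic regression via iteratively reweighted least squares.

Weights enter as frequency-style multipliers of the Bernoulli log-likelihood
(a pseudo-likelihood, the standard treatment of survey weights in a point
estimator). No model-based standard errors are produced: all interval
estimation in this package goes through the percentile bootstrap, so the only
quantities a fit carries are the coefficient vector and its convergence /
separation diagnostics.

Categorical terms are indicator-coded against an explicit reference level
(the first level listed on the term). Coefficient names follow the
``column[level]`` convention, interactions are named ``a:b``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, solve
from scipy.special import expit, log_expit

from .errors import ConvergenceWarning, EstimationError, InputError

INTERCEPT = "(intercept)"

#: IRLS stopping rule: relative deviance change below this, or `MAX_ITER` hit.
TOLERANCE = 1e-8
MAX_ITER = 100

#: Separation heuristics: a fitted probability within EPS of 0/1 at
#: convergence, or any coefficient larger than COEF_BOUND in magnitude.
SEPARATION_EPS = 1e-8
SEPARATION_COEF_BOUND = 15.0


@dataclass(frozen=True)
class Term:
    """One model term.

    ``levels=None`` marks a numeric (typically 0/1) column used as-is;
    otherwise the column is treated as categorical and indicator-coded
    against ``levels[0]``.
    """

    name: str
    levels: tuple[str, ...] | None = None

    @property
    def column_names(self) -> list[str]:
        if self.levels is None:
            return [self.name]
        return [f"{self.name}[{lev}]" for lev in self.levels[1:]]


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of one weighted logistic model."""

    response: str
    terms: tuple[Term, ...]
    interaction: tuple[str, str] | None = None
    weight: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.terms:
            if t.name in seen:
                raise InputError(f"duplicate model term {t.name!r}")
            seen.add(t.name)
            if t.levels is not None and len(t.levels) < 2:
                raise InputError(f"categorical term {t.name!r} needs >= 2 levels")
        if self.interaction is not None:
            for name in self.interaction:
                if name not in seen:
                    raise InputError(
                        f"interaction component {name!r} is not a model term"
                    )

    @property
    def variable_columns(self) -> list[str]:
        return [self.response] + [t.name for t in self.terms]


@dataclass
class LogisticFit:
    """Result of a weighted logistic fit.

    ``coefficients`` is a named vector on the logit scale whose index matches
    the design columns produced by the model spec.
    """

    coefficients: pd.Series
    converged: bool
    n_used: int
    separation_detected: bool
    spec: ModelSpec = field(repr=False)


def build_design(table: pd.DataFrame, terms: Sequence[Term],
                 interaction: tuple[str, str] | None = None
                 ) -> tuple[np.ndarray, list[str]]:
    """Assemble the design matrix (with intercept) for ``terms``."""
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = [INTERCEPT]
    for t in terms:
        if t.name not in table.columns:
            raise InputError(f"model column {t.name!r} not in table")
        if t.levels is None:
            cols.append(table[t.name].to_numpy(dtype=float))
            names.append(t.name)
        else:
            values = table[t.name].astype(object).to_numpy()
            known = set(t.levels)
            bad = {v for v in values if v not in known}
            if bad:
                raise InputError(
                    f"column {t.name!r} has levels {sorted(map(str, bad))} "
                    f"outside {list(t.levels)}"
                )
            for lev in t.levels[1:]:
                cols.append((values == lev).astype(float))
                names.append(f"{t.name}[{lev}]")
    if interaction is not None:
        a, b = interaction
        cols.append(table[a].to_numpy(dtype=float)
                    * table[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def _deviance(X: np.ndarray, y: np.ndarray, w: np.ndarray,
              beta: np.ndarray) -> float:
    eta = X @ beta
    return -2.0 * float(np.sum(w * (y * log_expit(eta)
                                    + (1.0 - y) * log_expit(-eta))))


def irls(X: np.ndarray, y: np.ndarray, w: np.ndarray,
         beta0: np.ndarray | None = None,
         tol: float = TOLERANCE, max_iter: int = MAX_ITER
         ) -> tuple[np.ndarray, bool, bool]:
    """Newton/IRLS maximisation of the weighted Bernoulli log-likelihood.

    Returns ``(beta, converged, separation_detected)``. Step-halving guards
    against overshooting; a singular information matrix is ridged once and
    otherwise reported as non-convergence.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    dev = _deviance(X, y, w, beta)
    converged = False
    mu = np.full(n, 0.5)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        wdiag = w * mu * (1.0 - mu)
        info = (X * wdiag[:, None]).T @ X
        score = X.T @ (w * (y - mu))
        try:
            step = solve(info, score, assume_a="pos")
        except LinAlgError:
            info = info + 1e-10 * np.eye(p) * (1.0 + np.trace(info))
            step = solve(info, score, assume_a="pos")
        new_beta = beta + step
        new_dev = _deviance(X, y, w, new_beta)
        for _half in range(25):
            if np.isfinite(new_dev) and new_dev <= dev + 1e-12:
                break
            step = step / 2.0
            new_beta = beta + step
            new_dev = _deviance(X, y, w, new_beta)
        beta = new_beta
        if abs(dev - new_dev) <= tol * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    mu = expit(X @ beta)
    separation = bool(
        (mu < SEPARATION_EPS).any()
        or (mu > 1.0 - SEPARATION_EPS).any()
        or (np.abs(beta) > SEPARATION_COEF_BOUND).any()
    )
    return beta, converged, separation


def fit_weighted_logistic(spec: ModelSpec, table: pd.DataFrame,
                          start: np.ndarray | None = None) -> LogisticFit:
    """Fit ``spec`` on ``table`` after listwise deletion over its variables.

    Raises
    ------
    EstimationError
        If no rows survive deletion or the response is constant.
    """
    cols = spec.variable_columns + ([spec.weight] if spec.weight else [])
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise InputError(f"columns missing from table: {missing}")
    data = table.dropna(subset=cols)
    if len(data) == 0:
        raise EstimationError("no complete cases for model "
                              f"{spec.response!r}")
    y = data[spec.response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise InputError(f"response {spec.response!r} must be binary 0/1")
    if y.min() == y.max():
        raise EstimationError(
            f"response {spec.response!r} is constant after listwise deletion"
        )
    if spec.weight is None:
        w = np.ones(len(data))
    else:
        w = data[spec.weight].to_numpy(dtype=float)
        if not (w > 0).all():
            raise InputError("weights must be strictly positive")
    X, names = build_design(data, spec.terms, spec.interaction)
    beta, converged, separation = irls(X, y, w, beta0=start)
    if not converged:
        warnings.warn(
            f"IRLS for {spec.response!r} did not converge in {MAX_ITER} "
            "iterations; returning last iterate",
            ConvergenceWarning,
            stacklevel=2,
        )
    return LogisticFit(
        coefficients=pd.Series(beta, index=names),
        converged=converged,
        n_used=len(data),
        separation_detected=separation,
        spec=spec,
    )


def predict_prob(fit: LogisticFit, setting: Mapping[str, object]) -> float:
    """Probability at a covariate ``setting`` (one value per model term)."""
    eta = float(fit.coefficients[INTERCEPT])
    for term in fit.spec.terms:
        if term.name not in setting:
            raise InputError(f"setting is missing model term {term.name!r}")
        value = setting[term.name]
        if term.levels is None:
            eta += float(fit.coefficients[term.name]) * float(value)  # type: ignore[arg-type]
        else:
            if value not in term.levels:
                raise InputError(
                    f"{value!r} is not a level of {term.name!r}"
                )
            if value != term.levels[0]:
                eta += float(fit.coefficients[f"{term.name}[{value}]"])
    if fit.spec.interaction is not None:
        a, b = fit.spec.interaction
        eta += (float(fit.coefficients[f"{a}:{b}"])
                * float(setting[a]) * float(setting[b]))  # type: ignore[arg-type]
    return float(expit(eta))
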