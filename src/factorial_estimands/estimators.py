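"""Estimators for 2x2 factorial trials: four analysis models and contrasts.

Four regression models cover every analysis the estimand framework needs,
all on the link scale implied by the chosen summary measure:

* ``factorial_adjusted`` — ``g(E[Y]) = alpha + beta_a Z_A + beta_b Z_B``;
  the at-the-margins estimator, adjusted for the other factor.  ``beta_a``
  is the primary estimator for the effect-of-A estimands and requires the
  no-interaction assumption for unbiasedness.
* ``factorial_unadjusted`` — ``g(E[Y]) = alpha + beta_a Z_A``; exposed only
  to demonstrate the noncollapsibility bias of omitting the other factor
  with an odds-ratio measure.  It is never routed to an estimand.
* ``multiarm`` — ``g(E[Y]) = alpha + beta_a0 Z_A0 + beta_0b Z_0B +
  beta_ab Z_AB`` with mutually exclusive cell dummies and the (0,0) cell as
  reference; the inside-the-table estimator, assumption-free for the
  cell-specific estimands.
* ``interaction`` — ``g(E[Y]) = alpha + beta_a Z_A + beta_b Z_B +
  beta_int Z_A Z_B``; a reparameterization of the multiarm model used to
  assess the no-interaction assumption.

Estimands map to estimators as: factorial strategy uses ``beta_a`` (or
``beta_a + beta_b`` for the combination estimand); multiarm uses
``beta_a0``, ``beta_ab - beta_0b``, ``beta_ab``; the usual-practice
estimand under the multiarm strategy uses the weighted contrast
``(1 - pi) beta_a0 + pi (beta_ab - beta_0b)`` with ``pi`` the assumed
proportion receiving B in routine care (treated as a known constant).

Inference is Wald on the link scale (normal reference for binary measures,
t with residual degrees of freedom for continuous least squares); ratio
measures are back-transformed by exponentiation, so natural-scale CI
endpoints are the exact monotone images of the link-scale ones.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cell_math import (
    LINK_FOR_MEASURE,
    RATIO_MEASURES,
    EstimandSpec,
    Link,
    Measure,
    OutcomeType,
    Target,
)
from .trial_data import CELLS, TrialDataset

__all__ = [
    "ModelKind",
    "Strategy",
    "FitError",
    "FitResult",
    "EffectEstimate",
    "fit_model",
    "linear_combination",
    "estimate_estimand",
    "weighted_usual_practice",
    "interaction_assessment",
]


class ModelKind(str, enum.Enum):
    FACTORIAL_ADJUSTED = "factorial_adjusted"
    FACTORIAL_UNADJUSTED = "factorial_unadjusted"
    MULTIARM = "multiarm"
    INTERACTION = "interaction"


class Strategy(str, enum.Enum):
    FACTORIAL = "factorial"
    MULTIARM = "multiarm"
    WEIGHTED_MULTIARM = "weighted_multiarm"
    TWO_STAGE = "two_stage"


MODEL_COEF_NAMES: Mapping[ModelKind, tuple] = {
    ModelKind.FACTORIAL_ADJUSTED: ("alpha", "beta_a", "beta_b"),
    ModelKind.FACTORIAL_UNADJUSTED: ("alpha", "beta_a"),
    ModelKind.MULTIARM: ("alpha", "beta_a0", "beta_0b", "beta_ab"),
    ModelKind.INTERACTION: ("alpha", "beta_a", "beta_b", "beta_int"),
}


class FitError(RuntimeError):
    """A model could not be fitted (non-convergence, separation, empty cells)."""


@dataclass
class FitResult:
    """Fitted coefficients with full covariance, on the link scale."""

    model: ModelKind
    measure: Measure
    names: tuple
    coef: dict  # name -> estimate (link scale)
    vcov: np.ndarray  # ordered as `names`
    n: int
    link: Link
    converged: bool = True
    n_iterations: int = 0
    df_resid: Optional[int] = None  # t-reference df (continuous LS only)

    def params(self) -> np.ndarray:
        return np.array([self.coef[name] for name in self.names])

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": self.model.value,
                "measure": self.measure.value,
                "link": self.link.value,
                "n": self.n,
                "coef": self.coef,
                "vcov": self.vcov.tolist(),
                "converged": self.converged,
                "n_iterations": self.n_iterations,
                "df_resid": self.df_resid,
            }
        )


@dataclass
class EffectEstimate:
    """A treatment contrast with Wald inference on the link scale.

    ``estimate_natural`` and the natural CI are the back-transformed (ratio
    scale for log/logit links, identical otherwise) versions of the
    link-scale values.
    """

    estimate_link: float
    se_link: float
    ci_low: float
    ci_high: float
    p_value: float
    estimate_natural: float
    ci_low_natural: float
    ci_high_natural: float
    measure: Measure
    level: float = 0.95
    strategy: Optional[Strategy] = None
    estimand: Optional[EstimandSpec] = None
    note: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "estimand": self.estimand.to_dict() if self.estimand else None,
            "strategy": self.strategy.value if self.strategy else None,
            "measure": self.measure.value,
            "estimate_link": self.estimate_link,
            "se_link": self.se_link,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "estimate_natural": self.estimate_natural,
            "ci_low_natural": self.ci_low_natural,
            "ci_high_natural": self.ci_high_natural,
            "level": self.level,
            "note": self.note,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: Mapping) -> "EffectEstimate":
        return cls(
            estimate_link=d["estimate_link"],
            se_link=d["se_link"],
            ci_low=d["ci_low"],
            ci_high=d["ci_high"],
            p_value=d["p_value"],
            estimate_natural=d["estimate_natural"],
            ci_low_natural=d["ci_low_natural"],
            ci_high_natural=d["ci_high_natural"],
            measure=Measure(d["measure"]),
            level=d.get("level", 0.95),
            strategy=Strategy(d["strategy"]) if d.get("strategy") else None,
            estimand=EstimandSpec.from_dict(d["estimand"]) if d.get("estimand") else None,
            note=d.get("note"),
        )


# ---------------------------------------------------------------------------
# design matrices and cell-support checks


def _design(data: TrialDataset, model: ModelKind) -> np.ndarray:
    za = data.df["z_a"].to_numpy(dtype=float)
    zb = data.df["z_b"].to_numpy(dtype=float)
    one = np.ones_like(za)
    if model is ModelKind.FACTORIAL_ADJUSTED:
        cols = [one, za, zb]
    elif model is ModelKind.FACTORIAL_UNADJUSTED:
        cols = [one, za]
    elif model is ModelKind.MULTIARM:
        cols = [one, za * (1 - zb), (1 - za) * zb, za * zb]
    else:
        cols = [one, za, zb, za * zb]
    return np.column_stack(cols)


def _check_support(data: TrialDataset, model: ModelKind) -> None:
    cell_n = {cell: int(data.cell_mask(*cell).sum()) for cell in CELLS}
    if model in (ModelKind.MULTIARM, ModelKind.INTERACTION):
        empty = [cell for cell, n in cell_n.items() if n == 0]
        if empty:
            raise FitError(
                f"{model.value} model requires all four cells non-empty; "
                f"empty cells: {empty}"
            )
    else:
        za = data.df["z_a"]
        margins = {"z_a=0": (za == 0).sum(), "z_a=1": (za == 1).sum()}
        if model is ModelKind.FACTORIAL_ADJUSTED:
            zb = data.df["z_b"]
            margins.update({"z_b=0": (zb == 0).sum(), "z_b=1": (zb == 1).sum()})
        empty_m = [m for m, n in margins.items() if n == 0]
        if empty_m:
            raise FitError(f"{model.value} model requires non-empty margins; empty: {empty_m}")


_MAX_ITER = 100
_IRLS_TOL = 1e-8
#: |coefficient| beyond this on the logit/log scale signals separation.
_SEPARATION_BOUND = 30.0


def fit_model(data: TrialDataset, model: ModelKind, measure: Measure) -> FitResult:
    """Fit one of the four analysis models on the measure's link scale.

    Binary measures use maximum likelihood (IRLS) for the logit and log
    links, and identity-link least squares with heteroskedasticity-robust
    covariance for the risk difference.  Continuous outcomes use ordinary
    least squares.
    """
    model = ModelKind(model)
    measure = Measure(measure)
    if measure is Measure.MEAN_DIFFERENCE and data.outcome_type is not OutcomeType.CONTINUOUS:
        raise ValueError("mean_difference requires a continuous outcome")
    if measure is not Measure.MEAN_DIFFERENCE and data.outcome_type is not OutcomeType.BINARY:
        raise ValueError(f"{measure.value} requires a binary outcome")
    _check_support(data, model)

    X = _design(data, model)
    y = data.df["y"].to_numpy(dtype=float)
    names = MODEL_COEF_NAMES[model]
    link = LINK_FOR_MEASURE[measure]
    df_resid: Optional[int] = None

    if measure is Measure.MEAN_DIFFERENCE:
        res = sm.OLS(y, X).fit()
        params, vcov = res.params, res.cov_params()
        converged, n_iter = True, 0
        df_resid = int(res.df_resid)
    elif measure is Measure.RISK_DIFFERENCE:
        # identity-link least squares on 0/1 outcomes; sandwich covariance
        # because the Bernoulli residual variance depends on the mean
        res = sm.OLS(y, X).fit(cov_type="HC1")
        params, vcov = res.params, res.cov_params()
        converged, n_iter = True, 0
    else:
        family = sm.families.Binomial(
            link=sm.families.links.Logit() if link is Link.LOGIT else sm.families.links.Log()
        )
        try:
            res = sm.GLM(y, X, family=family).fit(maxiter=_MAX_ITER, tol=_IRLS_TOL)
        except (PerfectSeparationError, ValueError, np.linalg.LinAlgError) as exc:
            raise FitError(f"{model.value} ({measure.value}) failed to fit: {exc}") from exc
        params, vcov = res.params, res.cov_params()
        converged = bool(getattr(res, "converged", True))
        n_iter = len(res.fit_history.get("deviance", [])) if hasattr(res, "fit_history") else 0
        if not converged:
            raise FitError(
                f"{model.value} ({measure.value}) did not converge in {_MAX_ITER} iterations"
            )
        big_se = np.sqrt(np.abs(np.diag(np.asarray(vcov, dtype=float)))).max() > 1e3
        if (
            np.max(np.abs(params)) > _SEPARATION_BOUND
            or big_se
            or not np.all(np.isfinite(vcov))
        ):
            cell_n = {cell: int(data.cell_mask(*cell).sum()) for cell in CELLS}
            raise FitError(
                f"{model.value} ({measure.value}): separation suspected "
                f"(|coef| > {_SEPARATION_BOUND}); cell sizes {cell_n}"
            )

    vcov = np.asarray(vcov, dtype=float)
    return FitResult(
        model=model,
        measure=measure,
        names=names,
        coef={name: float(b) for name, b in zip(names, params)},
        vcov=vcov,
        n=len(data),
        link=link,
        converged=converged,
        n_iterations=n_iter,
        df_resid=df_resid,
    )


# ---------------------------------------------------------------------------
# contrasts


def linear_combination(
    fit: FitResult,
    weights: Mapping[str, float],
    level: float = 0.95,
    strategy: Optional[Strategy] = None,
    estimand: Optional[EstimandSpec] = None,
    note: Optional[str] = None,
) -> EffectEstimate:
    """Wald inference for a linear contrast ``w' beta`` of fitted coefficients.

    The variance is ``w' V w`` with V the full coefficient covariance; the
    reference distribution is normal, or t with residual degrees of freedom
    for continuous least-squares fits.
    """
    unknown = set(weights) - set(fit.names)
    if unknown:
        raise ValueError(f"unknown coefficient names {sorted(unknown)}; model has {fit.names}")
    w = np.array([weights.get(name, 0.0) for name in fit.names])
    est = float(w @ fit.params())
    var = float(w @ fit.vcov @ w)
    se = math.sqrt(max(var, 0.0))

    alpha = 1.0 - level
    # a numerically zero SE (noiseless least squares) makes the Wald ratio
    # meaningless float noise; report p = 1 for a (numerically) null contrast
    # and p = 0 for a nonzero one
    degenerate = se <= 1e-12 * max(1.0, abs(est))
    if degenerate:
        p = 1.0 if abs(est) <= 1e-8 else 0.0
        crit = 0.0
    elif fit.df_resid is not None:
        crit = stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid)
        p = 2.0 * stats.t.sf(abs(est) / se, fit.df_resid)
    else:
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
        p = 2.0 * stats.norm.sf(abs(est) / se)
    lo, hi = est - crit * se, est + crit * se

    ratio = fit.measure in RATIO_MEASURES
    return EffectEstimate(
        estimate_link=est,
        se_link=se,
        ci_low=lo,
        ci_high=hi,
        p_value=float(min(p, 1.0)),
        estimate_natural=math.exp(est) if ratio else est,
        ci_low_natural=math.exp(lo) if ratio else lo,
        ci_high_natural=math.exp(hi) if ratio else hi,
        measure=fit.measure,
        level=level,
        strategy=strategy,
        estimand=estimand,
        note=note,
    )


def weighted_usual_practice(
    fit: FitResult, pi: float, level: float = 0.95, estimand: Optional[EstimandSpec] = None
) -> EffectEstimate:
    """Weighted usual-practice contrast ``(1-pi) beta_a0 + pi (beta_ab - beta_0b)``.

    ``pi`` — the assumed proportion receiving B under usual practice — is a
    fixed constant and contributes no variance.  Unbiased when receipt of B
    does not depend on A and cell-level effects are assignment-mechanism
    invariant.
    """
    if fit.model is not ModelKind.MULTIARM:
        raise ValueError("weighted usual-practice contrast requires a multiarm fit")
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi={pi} must lie in [0, 1]")
    weights = {"beta_a0": 1.0 - pi, "beta_ab": pi, "beta_0b": -pi}
    return linear_combination(
        fit, weights, level=level, strategy=Strategy.WEIGHTED_MULTIARM, estimand=estimand
    )


_NO_MARGINAL_OR_NOTE = (
    "no unbiased estimator is available for the marginal odds-ratio "
    "usual-practice estimand; the reported value targets the conditional effect"
)


def estimate_estimand(
    data: TrialDataset,
    spec: EstimandSpec,
    strategy: Strategy,
    level: float = 0.95,
) -> EffectEstimate:
    """Estimate an estimand with the factorial or multiarm strategy.

    The factorial strategy always fits the adjusted model (omitting the
    other factor biases noncollapsible measures); the multiarm strategy
    forms the direct cell contrast, routing the usual-practice estimand to
    the pi-weighted contrast.
    """
    strategy = Strategy(strategy)
    note = None
    if (
        spec.target is Target.A_USUAL_PRACTICE
        and spec.measure is Measure.ODDS_RATIO
        and spec.up_scale == "marginal"
    ):
        note = _NO_MARGINAL_OR_NOTE

    if strategy is Strategy.FACTORIAL:
        fit = fit_model(data, ModelKind.FACTORIAL_ADJUSTED, spec.measure)
        if spec.target is Target.A_PLUS_B:
            weights = {"beta_a": 1.0, "beta_b": 1.0}
        else:
            weights = {"beta_a": 1.0}
        return linear_combination(
            fit, weights, level=level, strategy=strategy, estimand=spec, note=note
        )

    if strategy in (Strategy.MULTIARM, Strategy.WEIGHTED_MULTIARM):
        fit = fit_model(data, ModelKind.MULTIARM, spec.measure)
        if spec.target is Target.A_USUAL_PRACTICE:
            if spec.pi is None:
                raise ValueError("multiarm usual-practice estimation requires pi")
            out = weighted_usual_practice(fit, spec.pi, level=level, estimand=spec)
            out.note = note
            return out
        weights = {
            Target.A_GIVEN_NO_B: {"beta_a0": 1.0},
            Target.A_GIVEN_B: {"beta_ab": 1.0, "beta_0b": -1.0},
            Target.A_PLUS_B: {"beta_ab": 1.0},
        }[spec.target]
        return linear_combination(
            fit, weights, level=level, strategy=Strategy.MULTIARM, estimand=spec
        )

    raise ValueError(
        f"strategy {strategy.value} is not a direct estimation strategy; "
        "use evaluation.two_stage_estimator for the (discouraged) two-stage procedure"
    )


def interaction_assessment(
    data: TrialDataset, measure: Measure, level: float = 0.95
) -> EffectEstimate:
    """Estimate the A-by-B interaction with CI and p-value.

    Fits the interaction model and reports ``beta_int`` on the link scale
    (and the ratio-of-ratios scale for log/logit links).  This model is a
    reparameterization of the multiarm model and is used only to assess the
    no-interaction assumption, never for the factorial main effects.
    """
    fit = fit_model(data, ModelKind.INTERACTION, measure)
    return linear_combination(fit, {"beta_int": 1.0}, level=level)
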