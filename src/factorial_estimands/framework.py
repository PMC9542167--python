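"""Four-step estimand framework for factorial trials, end to end.

Given a trial dataset and one or more declared estimands (exactly one
flagged primary), the framework

1. records the estimand declarations, including free-text labels for how
   intercurrent events affecting each treatment are handled (labels are
   recorded, not computed — only the treatment-policy strategy affects the
   arithmetic);
2. computes the primary analysis: the adjusted factorial estimate of each
   declared estimand;
3. assesses the no-interaction assumption: the estimated interaction with
   confidence interval, p-value, and the fold-range between the CI limits
   as an imprecision diagnostic;
4. computes the sensitivity analysis: the matching multiarm (or pi-weighted
   multiarm) estimate, and classifies the concordance between primary and
   sensitivity results.

The concordance rule — consistent when each point estimate lies inside the
other's confidence interval, discordant when the point estimates sit on
opposite sides of the null, indeterminate otherwise — is this package's
operationalization of "results broadly agree" and is a convention, not a
statistic with guaranteed properties.

All numbers are produced by the estimators module; the framework adds
orchestration, never recomputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .cell_math import RATIO_MEASURES, EstimandSpec, Measure, Target
from .estimators import (
    EffectEstimate,
    Strategy,
    estimate_estimand,
    interaction_assessment,
)
from .trial_data import TrialDataset

__all__ = [
    "EstimandDeclaration",
    "FrameworkReport",
    "run_framework",
    "render_report",
    "classify_concordance",
]


@dataclass(frozen=True)
class EstimandDeclaration:
    """A declared estimand with its role and intercurrent-event labels."""

    spec: EstimandSpec
    primary: bool = False
    label: str = ""
    intercurrent_strategy_a: str = "treatment policy"
    intercurrent_strategy_b: str = "treatment policy"

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "primary": self.primary,
            "label": self.label,
            "intercurrent_strategy_a": self.intercurrent_strategy_a,
            "intercurrent_strategy_b": self.intercurrent_strategy_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EstimandDeclaration":
        return cls(
            spec=EstimandSpec.from_dict(d["spec"]),
            primary=bool(d.get("primary", False)),
            label=d.get("label", ""),
            intercurrent_strategy_a=d.get("intercurrent_strategy_a", "treatment policy"),
            intercurrent_strategy_b=d.get("intercurrent_strategy_b", "treatment policy"),
        )


@dataclass
class EstimandResults:
    """Primary (factorial) and sensitivity (multiarm) estimates of one estimand."""

    declaration: EstimandDeclaration
    factorial: EffectEstimate
    multiarm: EffectEstimate

    def to_dict(self) -> dict:
        return {
            "declaration": self.declaration.to_dict(),
            "factorial": self.factorial.to_dict(),
            "multiarm": self.multiarm.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EstimandResults":
        return cls(
            declaration=EstimandDeclaration.from_dict(d["declaration"]),
            factorial=EffectEstimate.from_dict(d["factorial"]),
            multiarm=EffectEstimate.from_dict(d["multiarm"]),
        )


@dataclass
class FrameworkReport:
    """Structured output of the four-step framework."""

    declarations: List[EstimandDeclaration]
    results: List[EstimandResults]  # primary declaration first
    interaction_result: EffectEstimate
    interaction_ci_fold_range: Optional[float]  # ratio of natural CI limits
    concordance: str  # consistent | discordant | indeterminate
    concordance_trace: str
    level: float = 0.95

    @property
    def primary_result(self) -> EffectEstimate:
        return self.results[0].factorial

    @property
    def sensitivity_result(self) -> EffectEstimate:
        return self.results[0].multiarm

    def to_dict(self) -> dict:
        return {
            "declarations": [d.to_dict() for d in self.declarations],
            "results": [r.to_dict() for r in self.results],
            "interaction_result": self.interaction_result.to_dict(),
            "interaction_ci_fold_range": self.interaction_ci_fold_range,
            "concordance": self.concordance,
            "concordance_trace": self.concordance_trace,
            "level": self.level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameworkReport":
        return cls(
            declarations=[EstimandDeclaration.from_dict(x) for x in d["declarations"]],
            results=[EstimandResults.from_dict(x) for x in d["results"]],
            interaction_result=EffectEstimate.from_dict(d["interaction_result"]),
            interaction_ci_fold_range=d.get("interaction_ci_fold_range"),
            concordance=d["concordance"],
            concordance_trace=d["concordance_trace"],
            level=d.get("level", 0.95),
        )


def classify_concordance(
    primary: EffectEstimate, sensitivity: EffectEstimate
) -> Tuple[str, str]:
    """Classify agreement between a primary and a sensitivity estimate.

    Symmetric in its two arguments: consistent iff each link-scale point
    estimate lies inside the other's CI; discordant iff the point estimates
    lie strictly on opposite sides of the null; indeterminate otherwise.
    """
    # tolerance keeps degenerate zero-width CIs (noiseless fits) from
    # tripping on float rounding
    eps = 1e-9 * max(1.0, abs(primary.estimate_link), abs(sensitivity.estimate_link))
    p_in_s = sensitivity.ci_low - eps <= primary.estimate_link <= sensitivity.ci_high + eps
    s_in_p = primary.ci_low - eps <= sensitivity.estimate_link <= primary.ci_high + eps
    if p_in_s and s_in_p:
        return (
            "consistent",
            "each point estimate lies within the other's confidence interval",
        )
    if primary.estimate_link * sensitivity.estimate_link < 0:
        return (
            "discordant",
            "point estimates lie on opposite sides of the null on the link scale",
        )
    return (
        "indeterminate",
        "estimates agree in direction but at least one lies outside the other's CI",
    )


def _sensitivity_strategy(spec: EstimandSpec) -> Strategy:
    if spec.target is Target.A_USUAL_PRACTICE:
        return Strategy.WEIGHTED_MULTIARM
    return Strategy.MULTIARM


def run_framework(
    data: TrialDataset,
    declarations: Sequence[EstimandDeclaration],
    level: float = 0.95,
) -> FrameworkReport:
    """Execute the four-step framework on a dataset.

    Requires at least one declaration with exactly one flagged primary.
    The interaction assessment uses the primary estimand's measure.
    """
    if len(data) == 0:
        raise ValueError("cannot run the framework on an empty dataset")
    declarations = list(declarations)
    if not declarations:
        raise ValueError("at least one estimand declaration is required")
    n_primary = sum(d.primary for d in declarations)
    if n_primary != 1:
        raise ValueError(f"exactly one declaration must be primary (got {n_primary})")
    ordered = sorted(declarations, key=lambda d: not d.primary)

    results = []
    for decl in ordered:
        factorial = estimate_estimand(data, decl.spec, Strategy.FACTORIAL, level=level)
        multiarm = estimate_estimand(
            data, decl.spec, _sensitivity_strategy(decl.spec), level=level
        )
        results.append(EstimandResults(declaration=decl, factorial=factorial, multiarm=multiarm))

    primary_measure = ordered[0].spec.measure
    interaction = interaction_assessment(data, primary_measure, level=level)
    if primary_measure in RATIO_MEASURES and interaction.ci_low_natural > 0:
        fold = interaction.ci_high_natural / interaction.ci_low_natural
    else:
        fold = None

    concordance, trace = classify_concordance(results[0].factorial, results[0].multiarm)
    return FrameworkReport(
        declarations=ordered,
        results=results,
        interaction_result=interaction,
        interaction_ci_fold_range=fold,
        concordance=concordance,
        concordance_trace=trace,
        level=level,
    )


_TARGET_LABEL = {
    Target.A_GIVEN_NO_B: "A alone vs control alone",
    Target.A_GIVEN_B: "A with B vs control with B",
    Target.A_USUAL_PRACTICE: "A with usual-practice B vs control with usual-practice B",
    Target.A_PLUS_B: "A with B vs control alone",
}

_MEASURE_LABEL = {
    Measure.MEAN_DIFFERENCE: "mean difference",
    Measure.RISK_DIFFERENCE: "risk difference",
    Measure.RISK_RATIO: "risk ratio",
    Measure.ODDS_RATIO: "odds ratio",
}


def _fmt(est: EffectEstimate) -> str:
    return (
        f"{est.estimate_natural:.2f} "
        f"({est.ci_low_natural:.2f}, {est.ci_high_natural:.2f})"
    )


def render_report(report: FrameworkReport, format: str = "text") -> str:
    """Render a framework report as lossless JSON or a compact text table."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2)
    if format != "text":
        raise ValueError("format must be 'json' or 'text'")

    lines = []
    lines.append("Estimand framework report")
    lines.append("=" * 72)
    for res in report.results:
        decl = res.declaration
        role = "primary" if decl.primary else "supplementary"
        target = decl.spec.target
        lines.append(
            f"Estimand ({role}): {_TARGET_LABEL[target]} "
            f"[{_MEASURE_LABEL[decl.spec.measure]}"
            + (f", pi={decl.spec.pi:g}" if decl.spec.pi is not None else "")
            + "]"
        )
        lines.append(f"  Primary (factorial, adjusted): {_fmt(res.factorial)}")
        lines.append(f"  Sensitivity ({res.multiarm.strategy.value}): {_fmt(res.multiarm)}")
        if res.factorial.note:
            lines.append(f"  Note: {res.factorial.note}")
    inter = report.interaction_result
    lines.append(
        f"Interaction: {_fmt(inter)}, p = {inter.p_value:.3f}"
        + (
            f" ({report.interaction_ci_fold_range:.0f}-fold CI range)"
            if report.interaction_ci_fold_range is not None
            else ""
        )
    )
    lines.append(f"Concordance: {report.concordance} — {report.concordance_trace}")
    return "\n".join(lines)
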