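"""Closed-form effect-measure arithmetic on cell-level outcome parameters.

A 2x2 factorial trial has four treatment cells indexed by the pair
``(z_a, z_b)``.  Given the true outcome parameter of each cell (an event
probability for a binary outcome, a mean for a continuous one), every
population-level quantity of interest — stratum-specific (conditional)
effects, marginal effects under a mixing proportion for treatment B,
interaction contrasts, and the four treatment-A estimands — has an exact
closed form.  This module computes those values; everything downstream
(estimator consistency checks, simulation-study truth) is validated against
them.

Effect measures and their link scales
-------------------------------------
============== =========== =============================
measure        link        natural-scale effect
============== =========== =============================
mean_difference identity   mu1 - mu0
risk_difference identity   p1 - p0
risk_ratio      log        p1 / p0
odds_ratio      logit      odds(p1) / odds(p0)
============== =========== =============================

"No interaction" is always a statement about a scale: the interaction
contrast is zero on the link scale of the chosen measure.  The odds ratio is
noncollapsible — with a common stratum odds ratio and unequal stratum
baseline risks, the marginal odds ratio differs from (is attenuated toward 1
relative to) the conditional one, even though treatment B is randomized and
hence no confounder.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional

__all__ = [
    "OutcomeType",
    "Measure",
    "Target",
    "Link",
    "CellParams",
    "EstimandSpec",
    "EstimandUndefinedError",
    "LINK_FOR_MEASURE",
    "conditional_effect",
    "marginal_effect",
    "usual_practice_marginal_effect",
    "interaction_on_scale",
    "true_estimand_value",
    "link_transform",
    "inverse_link_difference",
]


class OutcomeType(str, enum.Enum):
    BINARY = "binary"
    CONTINUOUS = "continuous"


class Measure(str, enum.Enum):
    MEAN_DIFFERENCE = "mean_difference"
    RISK_DIFFERENCE = "risk_difference"
    RISK_RATIO = "risk_ratio"
    ODDS_RATIO = "odds_ratio"


class Target(str, enum.Enum):
    """The four treatment-A estimands of a two-trials-in-one factorial design."""

    A_GIVEN_NO_B = "A_GIVEN_NO_B"  # effect of A if nobody received B
    A_GIVEN_B = "A_GIVEN_B"  # effect of A if everybody received B
    A_USUAL_PRACTICE = "A_USUAL_PRACTICE"  # effect of A with B given as in routine care
    A_PLUS_B = "A_PLUS_B"  # combination A+B versus neither


class Link(str, enum.Enum):
    IDENTITY = "identity"
    LOG = "log"
    LOGIT = "logit"


LINK_FOR_MEASURE: Mapping[Measure, Link] = {
    Measure.MEAN_DIFFERENCE: Link.IDENTITY,
    Measure.RISK_DIFFERENCE: Link.IDENTITY,
    Measure.RISK_RATIO: Link.LOG,
    Measure.ODDS_RATIO: Link.LOGIT,
}

#: Measures whose natural scale is a ratio (link effect is a log).
RATIO_MEASURES = frozenset({Measure.RISK_RATIO, Measure.ODDS_RATIO})


class EstimandUndefinedError(ValueError):
    """Raised when a requested estimand has no well-defined true value.

    The conditional usual-practice estimand exists only when the effect of A
    is the same in both B strata on the link scale; otherwise there is no
    single stratum-specific effect to report.
    """


def _require_binary_measure(measure: Measure, outcome_type: OutcomeType) -> None:
    if measure is Measure.MEAN_DIFFERENCE and outcome_type is not OutcomeType.CONTINUOUS:
        raise ValueError("mean_difference requires a continuous outcome")
    if measure is not Measure.MEAN_DIFFERENCE and outcome_type is not OutcomeType.BINARY:
        raise ValueError(f"{measure.value} requires a binary outcome")


@dataclass(frozen=True)
class CellParams:
    """True outcome parameter of each factorial cell.

    ``p_ab`` is the event probability (binary outcome) or mean (continuous
    outcome) of the cell with ``z_a = a`` and ``z_b = b``.  ``sigma`` is the
    common residual standard deviation of a continuous outcome.
    """

    p00: float
    p10: float
    p01: float
    p11: float
    outcome_type: OutcomeType = OutcomeType.BINARY
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome_type", OutcomeType(self.outcome_type))
        if self.outcome_type is OutcomeType.BINARY:
            for name in ("p00", "p10", "p01", "p11"):
                p = getattr(self, name)
                if not 0.0 < p < 1.0:
                    raise ValueError(
                        f"binary cell probability {name}={p} must lie strictly in (0, 1)"
                    )
        else:
            # sigma = 0 is permitted as the degenerate noiseless case used by
            # exactness checks; negative values are rejected.
            if self.sigma is None or self.sigma < 0:
                raise ValueError("continuous outcomes require sigma >= 0")

    def cell(self, z_a: int, z_b: int) -> float:
        return {(0, 0): self.p00, (1, 0): self.p10, (0, 1): self.p01, (1, 1): self.p11}[
            (int(z_a), int(z_b))
        ]

    @classmethod
    def from_dict(cls, d: Mapping) -> "CellParams":
        return cls(
            p00=float(d["p00"]),
            p10=float(d["p10"]),
            p01=float(d["p01"]),
            p11=float(d["p11"]),
            outcome_type=OutcomeType(d.get("outcome_type", "binary")),
            sigma=float(d["sigma"]) if d.get("sigma") is not None else None,
        )

    def to_dict(self) -> dict:
        return {
            "p00": self.p00,
            "p10": self.p10,
            "p01": self.p01,
            "p11": self.p11,
            "outcome_type": self.outcome_type.value,
            "sigma": self.sigma,
        }


@dataclass(frozen=True)
class EstimandSpec:
    """Which treatment-A estimand is targeted, on which summary measure.

    ``pi`` is the proportion of patients assumed to receive treatment B
    under usual practice; it is required for — and only meaningful for —
    the usual-practice estimand.  ``up_scale`` selects the marginal
    (population-averaged, the default) or conditional (stratum-specific)
    reading of the usual-practice estimand.
    """

    target: Target
    measure: Measure
    pi: Optional[float] = None
    up_scale: str = "marginal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", Target(self.target))
        object.__setattr__(self, "measure", Measure(self.measure))
        if self.target is Target.A_USUAL_PRACTICE:
            if self.pi is None:
                raise ValueError("usual-practice estimand requires pi")
            if not 0.0 <= self.pi <= 1.0:
                raise ValueError(f"pi={self.pi} must lie in [0, 1]")
        elif self.pi is not None:
            raise ValueError(f"pi is only meaningful for {Target.A_USUAL_PRACTICE.value}")
        if self.up_scale not in ("marginal", "conditional"):
            raise ValueError("up_scale must be 'marginal' or 'conditional'")

    @property
    def link(self) -> Link:
        return LINK_FOR_MEASURE[self.measure]

    @classmethod
    def from_dict(cls, d: Mapping) -> "EstimandSpec":
        return cls(
            target=Target(d["target"]),
            measure=Measure(d["measure"]),
            pi=float(d["pi"]) if d.get("pi") is not None else None,
            up_scale=d.get("up_scale", "marginal"),
        )

    def to_dict(self) -> dict:
        return {
            "target": self.target.value,
            "measure": self.measure.value,
            "pi": self.pi,
            "up_scale": self.up_scale,
        }


# ---------------------------------------------------------------------------
# link-scale helpers


def link_transform(value: float, link: Link) -> float:
    """Apply a link function to an outcome parameter (probability or mean)."""
    if link is Link.IDENTITY:
        return value
    if link is Link.LOG:
        if value <= 0.0:
            raise ValueError(f"log link undefined at {value}")
        return math.log(value)
    if value <= 0.0 or value >= 1.0:
        raise ValueError(f"logit link undefined at probability {value}")
    return math.log(value / (1.0 - value))


def inverse_link_difference(link_effect: float, measure: Measure) -> float:
    """Map a link-scale effect back to the measure's natural scale."""
    return math.exp(link_effect) if measure in RATIO_MEASURES else link_effect


def _link_effect(p1: float, p0: float, measure: Measure) -> float:
    link = LINK_FOR_MEASURE[measure]
    return link_transform(p1, link) - link_transform(p0, link)


def _natural_effect(p1: float, p0: float, measure: Measure) -> float:
    return inverse_link_difference(_link_effect(p1, p0, measure), measure)


# ---------------------------------------------------------------------------
# operations


def conditional_effect(cells: CellParams, stratum_b: int, measure: Measure) -> float:
    """Effect of A vs no-A within one stratum of B, on the natural scale.

    Ratio measures are returned as ratios (not logs); boundary probabilities
    raise rather than being continuity-corrected, so the value is exact.
    """
    measure = Measure(measure)
    _require_binary_measure(measure, cells.outcome_type)
    if stratum_b not in (0, 1):
        raise ValueError("stratum_b must be 0 or 1")
    return _natural_effect(cells.cell(1, stratum_b), cells.cell(0, stratum_b), measure)


def usual_practice_marginal_effect(
    cells: CellParams,
    pi_given_a0: float,
    pi_given_a1: float,
    measure: Measure,
) -> float:
    """Marginal effect of A when B is received with arm-specific probability.

    Each treatment-A arm's outcome parameter is the mixture over receipt of B,
    ``(1 - pi) * p_{a0} + pi * p_{a1}``; the effect is then computed between
    the two mixtures.  Allowing the mixing proportion to differ by arm covers
    usual-practice mechanisms in which receipt of B depends on A.
    """
    measure = Measure(measure)
    _require_binary_measure(measure, cells.outcome_type)
    for pi in (pi_given_a0, pi_given_a1):
        if not 0.0 <= pi <= 1.0:
            raise ValueError(f"mixing proportion {pi} must lie in [0, 1]")
    m0 = (1.0 - pi_given_a0) * cells.cell(0, 0) + pi_given_a0 * cells.cell(0, 1)
    m1 = (1.0 - pi_given_a1) * cells.cell(1, 0) + pi_given_a1 * cells.cell(1, 1)
    return _natural_effect(m1, m0, measure)


def marginal_effect(cells: CellParams, pi_b: float, measure: Measure) -> float:
    """Marginal effect of A when a proportion ``pi_b`` of patients receive B.

    Collapses over the B strata before forming the contrast.  Exactly equals
    the common conditional effect for collapsible measures (risk difference,
    mean difference); differs for the odds ratio whenever stratum baseline
    risks differ (noncollapsibility).
    """
    return usual_practice_marginal_effect(cells, pi_b, pi_b, measure)


def interaction_on_scale(cells: CellParams, measure: Measure) -> float:
    """Interaction contrast of A and B on the measure's link scale.

    Returns ``(link effect of A | B=1) - (link effect of A | B=0)``; zero if
    and only if there is no interaction on that scale.  Interaction is
    scale-specific: cells with none on the log-odds scale generally show a
    nonzero risk-difference interaction.
    """
    measure = Measure(measure)
    _require_binary_measure(measure, cells.outcome_type)
    eff1 = _link_effect(cells.cell(1, 1), cells.cell(0, 1), measure)
    eff0 = _link_effect(cells.cell(1, 0), cells.cell(0, 0), measure)
    return eff1 - eff0


#: Agreement tolerance (link scale) under which the two stratum effects are
#: treated as one common effect, making the conditional usual-practice
#: estimand well defined.
CONDITIONAL_UP_TOL = 1e-8


def true_estimand_value(cells: CellParams, spec: EstimandSpec) -> float:
    """Exact true value of an estimand, on the measure's natural scale.

    Raises :class:`EstimandUndefinedError` for a conditional usual-practice
    estimand whose stratum effects disagree — an undefined estimand is
    signalled, never silently replaced by a number.
    """
    measure = spec.measure
    _require_binary_measure(measure, cells.outcome_type)
    if spec.target is Target.A_GIVEN_NO_B:
        return conditional_effect(cells, 0, measure)
    if spec.target is Target.A_GIVEN_B:
        return conditional_effect(cells, 1, measure)
    if spec.target is Target.A_PLUS_B:
        return _natural_effect(cells.cell(1, 1), cells.cell(0, 0), measure)
    # usual practice
    if spec.up_scale == "marginal":
        return marginal_effect(cells, spec.pi, measure)
    eff0 = _link_effect(cells.cell(1, 0), cells.cell(0, 0), measure)
    eff1 = _link_effect(cells.cell(1, 1), cells.cell(0, 1), measure)
    if abs(eff1 - eff0) > CONDITIONAL_UP_TOL:
        raise EstimandUndefinedError(
            "conditional usual-practice estimand is undefined: stratum effects "
            f"differ on the {spec.link.value} scale ({eff0:.6g} vs {eff1:.6g})"
        )
    return inverse_link_difference(0.5 * (eff0 + eff1), measure)
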