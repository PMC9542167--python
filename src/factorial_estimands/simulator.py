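"""Potential-outcomes data generator for 2x2 factorial trials.

Each simulated participant carries a full set of cell-level potential
outcomes implied by :class:`~factorial_estimands.cell_math.CellParams`; the
assignment mechanism then determines which one is observed.  Two mechanisms
are provided:

* factorial randomization — independent Bernoulli allocation to A and to B
  (independent coin flips rather than permuted blocks, which keeps oracle
  targets exact and is asymptotically equivalent);
* usual-practice cohorts — A randomized, B received with an arm-specific
  probability ``pi_b_given_a``, allowing receipt of B to depend on A (the
  mechanism under which the conditional usual-practice estimand becomes
  ill-defined).

An optional intercurrent-event mechanism models treatment discontinuation
as a per-cell Bernoulli event that shifts the discontinued participant's
outcome distribution; treatment labels stay as-randomized, so analyses of
the resulting data follow the treatment-policy strategy.

Every simulated trial carries a ``truth`` map of exact estimand values
recomputed from the generating cell parameters, the reference point for all
bias and coverage assessments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .cell_math import (
    CellParams,
    EstimandSpec,
    EstimandUndefinedError,
    Measure,
    OutcomeType,
    Target,
    true_estimand_value,
    usual_practice_marginal_effect,
)
from .trial_data import CELLS, TrialDataset

__all__ = [
    "UsualPracticeConfig",
    "IntercurrentConfig",
    "SimulationConfig",
    "SimulatedTrial",
    "simulate_factorial",
    "simulate_usual_practice",
    "apply_intercurrent_events",
]


def _check_prob(value: float, name: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} must lie in [0, 1]")
    return float(value)


@dataclass(frozen=True)
class UsualPracticeConfig:
    """Probability of receiving B under usual practice, by A arm."""

    pi_b_given_a0: float
    pi_b_given_a1: float

    def __post_init__(self) -> None:
        _check_prob(self.pi_b_given_a0, "pi_b_given_a0")
        _check_prob(self.pi_b_given_a1, "pi_b_given_a1")

    @property
    def depends_on_a(self) -> bool:
        return self.pi_b_given_a0 != self.pi_b_given_a1


@dataclass(frozen=True)
class IntercurrentConfig:
    """Treatment-discontinuation mechanism.

    ``disc_prob_by_cell`` maps each cell ``(z_a, z_b)`` to a discontinuation
    probability; a discontinued participant's outcome is redrawn with the
    cell parameter shifted by ``outcome_shift_on_disc`` (binary
    probabilities are clipped to [0.01, 0.99]).
    """

    disc_prob_by_cell: Mapping[Tuple[int, int], float]
    outcome_shift_on_disc: float = 0.0

    def __post_init__(self) -> None:
        probs = dict(self.disc_prob_by_cell)
        for cell in CELLS:
            _check_prob(probs.get(cell, 0.0), f"disc_prob{cell}")
        object.__setattr__(self, "disc_prob_by_cell", probs)

    def prob(self, cell: Tuple[int, int]) -> float:
        return float(self.disc_prob_by_cell.get(cell, 0.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated trial.

    The seed is mandatory: no simulation ever touches global random state.
    ``alloc_a``/``alloc_b`` are the Bernoulli allocation probabilities of
    the two independent randomizations (1:1 by default, as in the standard
    factorial design).
    """

    cells: CellParams
    n: int
    seed: int
    alloc_a: float = 0.5
    alloc_b: float = 0.5
    usual_practice: Optional[UsualPracticeConfig] = None
    intercurrent: Optional[IntercurrentConfig] = None

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"n={self.n} must be at least 4")
        if self.seed is None or int(self.seed) != self.seed:
            raise ValueError("an integer seed is required")
        _check_prob(self.alloc_a, "alloc_a")
        _check_prob(self.alloc_b, "alloc_b")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        up = d.get("usual_practice")
        ic = d.get("intercurrent")
        intercurrent = None
        if ic is not None:
            raw = ic["disc_prob_by_cell"]
            probs = {
                (int(k[0]), int(k[1])): float(v) for k, v in raw.items()
            } if isinstance(raw, Mapping) else {
                cell: float(p) for cell, p in zip(CELLS, raw)
            }
            intercurrent = IntercurrentConfig(
                disc_prob_by_cell=probs,
                outcome_shift_on_disc=float(ic.get("outcome_shift_on_disc", 0.0)),
            )
        return cls(
            cells=CellParams.from_dict(d["cells"]),
            n=int(d["n"]),
            seed=int(d["seed"]),
            alloc_a=float(d.get("alloc_a", 0.5)),
            alloc_b=float(d.get("alloc_b", 0.5)),
            usual_practice=UsualPracticeConfig(
                pi_b_given_a0=float(up["pi_b_given_a0"]),
                pi_b_given_a1=float(up["pi_b_given_a1"]),
            )
            if up is not None
            else None,
            intercurrent=intercurrent,
        )


@dataclass
class SimulatedTrial:
    """A simulated dataset together with the exact truth of each estimand.

    ``truth`` maps ``(target, measure)`` to the oracle value on the natural
    scale, or to ``None`` where the estimand is undefined (a conditional
    usual-practice estimand under A-dependent receipt of B).
    """

    data: TrialDataset
    truth: Dict[Tuple[Target, Measure], Optional[float]]
    config: SimulationConfig

    def truth_json(self) -> dict:
        return {
            f"{t.value}:{m.value}": v for (t, m), v in self.truth.items()
        }


def _compatible_measures(cells: CellParams):
    if cells.outcome_type is OutcomeType.BINARY:
        return (Measure.RISK_DIFFERENCE, Measure.RISK_RATIO, Measure.ODDS_RATIO)
    return (Measure.MEAN_DIFFERENCE,)


def _base_truth(cells: CellParams) -> Dict[Tuple[Target, Measure], Optional[float]]:
    truth: Dict[Tuple[Target, Measure], Optional[float]] = {}
    for measure in _compatible_measures(cells):
        for target in (Target.A_GIVEN_NO_B, Target.A_GIVEN_B, Target.A_PLUS_B):
            spec = EstimandSpec(target=target, measure=measure)
            truth[(target, measure)] = true_estimand_value(cells, spec)
    return truth


def _draw_outcomes(
    rng: np.random.Generator, cells: CellParams, za: np.ndarray, zb: np.ndarray
) -> np.ndarray:
    mu = (
        cells.p00 * (1 - za) * (1 - zb)
        + cells.p10 * za * (1 - zb)
        + cells.p01 * (1 - za) * zb
        + cells.p11 * za * zb
    ).astype(float)
    if cells.outcome_type is OutcomeType.BINARY:
        return rng.binomial(1, mu).astype(float)
    return mu + cells.sigma * rng.standard_normal(len(mu))


def _make_dataset(za: np.ndarray, zb: np.ndarray, y: np.ndarray, outcome_type) -> TrialDataset:
    df = pd.DataFrame(
        {
            "id": [str(i + 1) for i in range(len(y))],
            "z_a": za.astype(int),
            "z_b": zb.astype(int),
            "y": y,
        }
    )
    return TrialDataset(df=df, outcome_type=outcome_type)


def simulate_factorial(config: SimulationConfig) -> SimulatedTrial:
    """Simulate a 2x2 factorial randomization.

    Per participant: ``Z_A ~ Bernoulli(alloc_a)`` and ``Z_B ~
    Bernoulli(alloc_b)`` independently, then the outcome is drawn from the
    realized cell's distribution.  Deterministic given the seed.
    """
    if config.usual_practice is not None:
        raise ValueError("factorial simulation does not take a usual_practice block")
    rng = np.random.default_rng(config.seed)
    za = rng.binomial(1, config.alloc_a, size=config.n)
    zb = rng.binomial(1, config.alloc_b, size=config.n)
    y = _draw_outcomes(rng, config.cells, za, zb)
    data = _make_dataset(za, zb, y, config.cells.outcome_type)
    return SimulatedTrial(data=data, truth=_base_truth(config.cells), config=config)


def simulate_usual_practice(config: SimulationConfig) -> SimulatedTrial:
    """Simulate a cohort in which B is received according to usual practice.

    A is randomized; B is received with probability ``pi_b_given_a`` for the
    participant's A arm.  The truth map includes the marginal usual-practice
    estimand (well defined even under A-dependent receipt of B) and marks
    the conditional one undefined whenever the two receipt probabilities
    differ or the stratum effects disagree on the link scale.
    """
    up = config.usual_practice
    if up is None:
        raise ValueError("usual-practice simulation requires a usual_practice block")
    rng = np.random.default_rng(config.seed)
    za = rng.binomial(1, config.alloc_a, size=config.n)
    pi = np.where(za == 1, up.pi_b_given_a1, up.pi_b_given_a0)
    zb = rng.binomial(1, pi)
    y = _draw_outcomes(rng, config.cells, za, zb)
    data = _make_dataset(za, zb, y, config.cells.outcome_type)

    truth = _base_truth(config.cells)
    for measure in _compatible_measures(config.cells):
        truth[(Target.A_USUAL_PRACTICE, measure)] = usual_practice_marginal_effect(
            config.cells, up.pi_b_given_a0, up.pi_b_given_a1, measure
        )
    return SimulatedTrial(data=data, truth=truth, config=config)


def conditional_usual_practice_truth(
    trial: SimulatedTrial, measure: Measure
) -> Optional[float]:
    """Conditional usual-practice oracle for a usual-practice trial.

    Returns ``None`` (undefined) when receipt of B depends on A or the
    stratum effects disagree on the link scale.
    """
    up = trial.config.usual_practice
    if up is None or up.depends_on_a:
        return None
    spec = EstimandSpec(
        target=Target.A_USUAL_PRACTICE,
        measure=measure,
        pi=up.pi_b_given_a0,
        up_scale="conditional",
    )
    try:
        return true_estimand_value(trial.config.cells, spec)
    except EstimandUndefinedError:
        return None


def apply_intercurrent_events(trial: SimulatedTrial) -> SimulatedTrial:
    """Overlay a treatment-discontinuation mechanism on a simulated trial.

    Each participant discontinues with their cell's probability; a
    discontinued participant's outcome is redrawn from the cell distribution
    shifted by ``outcome_shift_on_disc``.  Randomized treatment labels are
    unchanged, so downstream analyses are treatment-policy by construction.
    The truth map still refers to the no-discontinuation potential outcomes;
    the gap between estimates on the modified data and that truth is the
    quantity of interest.
    """
    ic = trial.config.intercurrent
    if ic is None:
        raise ValueError("config has no intercurrent block")
    cells = trial.config.cells
    # independent stream, derived from (seed, 1) so it never replays the
    # allocation/outcome draws
    rng = np.random.default_rng([trial.config.seed, 1])
    df = trial.data.df
    za = df["z_a"].to_numpy()
    zb = df["z_b"].to_numpy()
    disc_p = np.array([ic.prob((a, b)) for a, b in zip(za, zb)])
    disc = rng.binomial(1, disc_p).astype(bool)
    if not disc.any():
        return trial

    y = df["y"].to_numpy(dtype=float).copy()
    mu = np.array([cells.cell(a, b) for a, b in zip(za[disc], zb[disc])])
    if cells.outcome_type is OutcomeType.BINARY:
        shifted = np.clip(mu + ic.outcome_shift_on_disc, 0.01, 0.99)
        y[disc] = rng.binomial(1, shifted).astype(float)
    else:
        y[disc] = mu + ic.outcome_shift_on_disc + cells.sigma * rng.standard_normal(disc.sum())
    new_df = df.copy()
    new_df["y"] = y
    data = TrialDataset(df=new_df, outcome_type=cells.outcome_type)
    return SimulatedTrial(data=data, truth=dict(trial.truth), config=trial.config)
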