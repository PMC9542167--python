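"""Monte-Carlo evaluation of factorial-trial estimators.

Repeated-simulation studies quantify, for each (estimand, strategy) pair,
the link-scale bias, empirical and mean model-based standard error, and
confidence-interval coverage against the exact cell-level oracle, plus the
rejection rate of the interaction test.  This is the machinery behind the
assumption matrix for factorial designs: factorial estimators are unbiased
only under no interaction, multiarm estimators unconditionally, and the
weighted usual-practice estimator only when receipt of B does not depend
on A.

The two-stage procedure — pre-testing the interaction and letting the test
outcome pick the estimator — is implemented solely as a negative control:
the pre-test makes the sampling distribution of the reported estimate a
mixture and distorts its coverage, which is why it is discouraged in favour
of reporting the factorial and multiarm analyses side by side.

Bias and coverage are assessed on the link scale (log odds ratio and so
on), where the estimators are asymptotically normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cell_math import (
    RATIO_MEASURES,
    EstimandSpec,
    Measure,
    true_estimand_value,
)
from .estimators import (
    EffectEstimate,
    FitError,
    Strategy,
    estimate_estimand,
    interaction_assessment,
)
from .simulator import (
    SimulatedTrial,
    SimulationConfig,
    apply_intercurrent_events,
    simulate_factorial,
    simulate_usual_practice,
)
from .trial_data import TrialDataset

__all__ = ["SimulationSummary", "run_simulation_study", "two_stage_estimator", "summaries_frame"]

logger = logging.getLogger(__name__)

#: Maximum tolerated fraction of replicates with failed fits.
MAX_FAILURE_FRACTION = 0.05


@dataclass
class SimulationSummary:
    """Operating characteristics of one (estimand, strategy) pair.

    All location quantities are on the link scale.  ``mc_error_bias`` is
    the Monte-Carlo standard error of the bias estimate,
    ``empirical_se / sqrt(n_reps)``.
    """

    estimand: EstimandSpec
    strategy: Strategy
    n_reps: int
    truth: float  # link scale
    mean_estimate: float
    bias: float
    mc_error_bias: float
    empirical_se: float
    mean_model_se: float
    coverage: float
    rejection_rate: Optional[float] = None  # interaction test, when assessed
    n_failed: int = 0

    def to_dict(self) -> dict:
        d = {
            "target": self.estimand.target.value,
            "measure": self.estimand.measure.value,
            "pi": self.estimand.pi,
            "strategy": self.strategy.value,
            "n_reps": self.n_reps,
            "truth_link": self.truth,
            "mean_estimate": self.mean_estimate,
            "bias": self.bias,
            "mc_error_bias": self.mc_error_bias,
            "empirical_se": self.empirical_se,
            "mean_model_se": self.mean_model_se,
            "coverage": self.coverage,
            "rejection_rate": self.rejection_rate,
            "n_failed": self.n_failed,
        }
        return d


def _truth_link(config: SimulationConfig, spec: EstimandSpec) -> float:
    value = true_estimand_value(config.cells, spec)
    return math.log(value) if spec.measure in RATIO_MEASURES else value


def two_stage_estimator(
    data: TrialDataset, spec: EstimandSpec, alpha: float = 0.05, level: float = 0.95
) -> EffectEstimate:
    """Interaction pre-test followed by a data-driven choice of estimator.

    If the interaction test's p-value is at least ``alpha``, the factorial
    estimate is returned, otherwise the multiarm estimate; the result is
    tagged ``two_stage``.  The pre-test biases downstream inference, so this
    exists as a documented negative control, not a recommended analysis.
    """
    inter = interaction_assessment(data, spec.measure, level=level)
    if inter.p_value >= alpha:
        out = estimate_estimand(data, spec, Strategy.FACTORIAL, level=level)
    else:
        out = estimate_estimand(data, spec, Strategy.MULTIARM, level=level)
    out.strategy = Strategy.TWO_STAGE
    return out


def _simulate(config: SimulationConfig) -> SimulatedTrial:
    if config.usual_practice is not None:
        trial = simulate_usual_practice(config)
    else:
        trial = simulate_factorial(config)
    if config.intercurrent is not None:
        trial = apply_intercurrent_events(trial)
    return trial


def run_simulation_study(
    config: SimulationConfig,
    specs: Sequence[EstimandSpec],
    strategies: Sequence[Strategy],
    n_reps: int,
    base_seed: int,
    level: float = 0.95,
    assess_interaction: bool = False,
    interaction_alpha: float = 0.05,
    two_stage_alpha: float = 0.05,
) -> List[SimulationSummary]:
    """Run a repeated-simulation study and summarise each (spec, strategy).

    Replicate ``r`` regenerates the trial with ``seed = base_seed + r``,
    estimates every spec under every strategy, and scores the replicate CI
    against the link-scale oracle.  Replicates whose fit fails are excluded
    with accounting; more than 5% failures for any pair is a hard error.
    When ``assess_interaction`` is set, the interaction test's rejection
    rate at ``interaction_alpha`` is recorded on every summary.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    strategies = [Strategy(s) for s in strategies]
    keys = [(spec, strategy) for spec in specs for strategy in strategies]
    draws: Dict[Tuple[int, int], List[Tuple[float, float, bool]]] = {
        (i, j): [] for i in range(len(specs)) for j in range(len(strategies))
    }
    failures: Dict[Tuple[int, int], int] = {k: 0 for k in draws}
    interaction_rejections: List[bool] = []
    truths = {i: _truth_link(config, spec) for i, spec in enumerate(specs)}

    for r in range(n_reps):
        rep_config = SimulationConfig(
            cells=config.cells,
            n=config.n,
            seed=int(base_seed) + r,
            alloc_a=config.alloc_a,
            alloc_b=config.alloc_b,
            usual_practice=config.usual_practice,
            intercurrent=config.intercurrent,
        )
        trial = _simulate(rep_config)
        if assess_interaction:
            try:
                inter = interaction_assessment(trial.data, specs[0].measure, level=level)
                interaction_rejections.append(inter.p_value < interaction_alpha)
            except FitError:
                pass
        for i, spec in enumerate(specs):
            for j, strategy in enumerate(strategies):
                try:
                    if strategy is Strategy.TWO_STAGE:
                        est = two_stage_estimator(
                            trial.data, spec, alpha=two_stage_alpha, level=level
                        )
                    else:
                        est = estimate_estimand(trial.data, spec, strategy, level=level)
                except FitError as exc:
                    failures[(i, j)] += 1
                    logger.debug("replicate %d failed for %s/%s: %s", r, spec, strategy, exc)
                    continue
                covered = est.ci_low <= truths[i] <= est.ci_high
                draws[(i, j)].append((est.estimate_link, est.se_link, covered))

    rejection_rate = (
        float(np.mean(interaction_rejections)) if interaction_rejections else None
    )
    summaries: List[SimulationSummary] = []
    for i, spec in enumerate(specs):
        for j, strategy in enumerate(strategies):
            n_failed = failures[(i, j)]
            if n_failed > MAX_FAILURE_FRACTION * n_reps:
                raise FitError(
                    f"{n_failed}/{n_reps} replicates failed for "
                    f"{spec.target.value}/{strategy.value} (> {MAX_FAILURE_FRACTION:.0%})"
                )
            rows = draws[(i, j)]
            ests = np.array([e for e, _, _ in rows])
            ses = np.array([s for _, s, _ in rows])
            covers = np.array([c for _, _, c in rows])
            k = len(rows)
            emp_se = float(ests.std(ddof=1)) if k > 1 else 0.0
            summaries.append(
                SimulationSummary(
                    estimand=spec,
                    strategy=strategy,
                    n_reps=k,
                    truth=truths[i],
                    mean_estimate=float(ests.mean()),
                    bias=float(ests.mean() - truths[i]),
                    mc_error_bias=emp_se / math.sqrt(k) if k else float("nan"),
                    empirical_se=emp_se,
                    mean_model_se=float(ses.mean()),
                    coverage=float(covers.mean()),
                    rejection_rate=rejection_rate,
                    n_failed=n_failed,
                )
            )
    return summaries


def summaries_frame(summaries: Sequence[SimulationSummary]) -> pd.DataFrame:
    """Tabulate a list of simulation summaries (one row per pair)."""
    return pd.DataFrame([s.to_dict() for s in summaries])
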