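"""Shared fixtures: reference cell parameters and deterministic dataset builders."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from factorial_estimands import CellParams, OutcomeType, TrialDataset

#: The illustrative binary cell probabilities used throughout: a trial where
#: A halves the odds in both B strata (conditional OR 0.50), B has OR 0.10,
#: and the marginal OR for A at 50% receiving B is 0.56.
TABLE_CELLS = CellParams(p00=0.50, p10=0.333, p01=0.091, p11=0.048)


@pytest.fixture
def table_cells() -> CellParams:
    return TABLE_CELLS


def logit(p: float) -> float:
    return math.log(p / (1 - p))


def invlogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def cells_with_logodds_interaction(
    p00: float, p10: float, p01: float, delta: float
) -> CellParams:
    """Binary cells with a chosen log-odds-ratio interaction ``delta``."""
    p11 = invlogit(logit(p01) + logit(p10) - logit(p00) + delta)
    return CellParams(p00=p00, p10=p10, p01=p01, p11=p11)


def balanced_continuous_dataset(
    cell_means, n_per_cell: int, sigma: float = 0.0, seed: int | None = None
) -> TrialDataset:
    """Balanced continuous dataset with exactly ``n_per_cell`` per cell.

    ``cell_means`` is (m00, m10, m01, m11).  With ``sigma = 0`` every
    outcome equals its cell mean exactly.
    """
    m00, m10, m01, m11 = cell_means
    rows = []
    rng = np.random.default_rng(seed) if sigma > 0 else None
    for (a, b), mu in zip([(0, 0), (1, 0), (0, 1), (1, 1)], [m00, m10, m01, m11]):
        y = np.full(n_per_cell, float(mu))
        if rng is not None:
            y = y + sigma * rng.standard_normal(n_per_cell)
        for yi in y:
            rows.append((a, b, yi))
    df = pd.DataFrame(rows, columns=["z_a", "z_b", "y"])
    return TrialDataset(df=df, outcome_type=OutcomeType.CONTINUOUS)


def balanced_binary_dataset(cells: CellParams, n_per_cell: int, seed: int) -> TrialDataset:
    """Balanced binary dataset: outcomes Bernoulli(cell probability)."""
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in [(0, 0), (1, 0), (0, 1), (1, 1)]:
        y = rng.binomial(1, cells.cell(a, b), size=n_per_cell)
        for yi in y:
            rows.append((a, b, float(yi)))
    df = pd.DataFrame(rows, columns=["z_a", "z_b", "y"])
    return TrialDataset(df=df, outcome_type=OutcomeType.BINARY)


@pytest.fixture
def noiseless_additive_data() -> TrialDataset:
    """Cell means (0, 1, 2, 3): additive, zero noise, 10 per cell."""
    return balanced_continuous_dataset((0.0, 1.0, 2.0, 3.0), n_per_cell=10)


@pytest.fixture
def noiseless_interaction_data() -> TrialDataset:
    """Cell means (0, 1, 2, 5): interaction 2, zero noise, 10 per cell."""
    return balanced_continuous_dataset((0.0, 1.0, 2.0, 5.0), n_per_cell=10)
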