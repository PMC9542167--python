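"""Participant-level data model and CSV I/O for 2x2 factorial trials.

A trial dataset is a flat table of records ``(id, z_a, z_b, y)`` where
``z_a`` and ``z_b`` are 0/1 allocation indicators for treatments A and B and
``y`` is the outcome (0/1 for a binary outcome, any real for a continuous
one).  Treatment coding is fixed at 0/1 with no factor-level remapping, which
removes a whole class of silent coding errors in downstream contrasts.

Rows with a missing outcome are dropped on read (complete-case analysis) and
the exclusion count is logged; analyses are treatment-policy on the observed
outcomes.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .cell_math import OutcomeType

__all__ = ["TrialDataset", "CellCounts", "read_trial_csv", "write_trial_csv", "cross_tabulate"]

logger = logging.getLogger(__name__)

CELLS = [(0, 0), (1, 0), (0, 1), (1, 1)]


@dataclass
class TrialDataset:
    """Participant-level records of a 2x2 factorial (or usual-practice) trial.

    ``df`` holds columns ``id`` (string), ``z_a``, ``z_b`` (int 0/1) and
    ``y`` (float).  Validation of the 0/1 coding happens at construction;
    the four-cell support required by multiarm models is checked at fit
    time, not here.
    """

    df: pd.DataFrame
    outcome_type: OutcomeType = OutcomeType.BINARY

    def __post_init__(self) -> None:
        self.outcome_type = OutcomeType(self.outcome_type)
        df = self.df
        missing = {"z_a", "z_b", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"dataset is missing required columns: {sorted(missing)}")
        if "id" not in df.columns:
            df = df.copy()
            df.insert(0, "id", [str(i + 1) for i in range(len(df))])
        df = df[["id", "z_a", "z_b", "y"]].copy()
        for col in ("z_a", "z_b"):
            vals = df[col].to_numpy()
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"column {col!r} must be 0/1; found {vals[bad][0]!r} in row {row + 1}"
                )
            df[col] = df[col].astype(np.int64)
        df["y"] = df["y"].astype(float)
        if df["y"].isna().any():
            raise ValueError("dataset contains missing outcomes; drop them before construction")
        if self.outcome_type is OutcomeType.BINARY:
            yvals = df["y"].to_numpy()
            bad = ~np.isin(yvals, (0.0, 1.0))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"binary outcome must be 0/1; found {yvals[bad][0]!r} in row {row + 1}"
                )
        df["id"] = df["id"].astype(str)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def cell_mask(self, z_a: int, z_b: int) -> np.ndarray:
        return ((self.df["z_a"] == z_a) & (self.df["z_b"] == z_b)).to_numpy()


@dataclass
class CellCounts:
    """Per-cell summary of a trial dataset.

    For binary outcomes, ``events`` holds the per-cell event counts; for
    continuous outcomes, ``sums`` and ``sumsq`` hold per-cell sums and sums
    of squares (sufficient statistics for cell means and variances).
    """

    outcome_type: OutcomeType
    n: dict = field(default_factory=dict)  # (a, b) -> count
    events: dict = field(default_factory=dict)  # binary only
    sums: dict = field(default_factory=dict)  # continuous only
    sumsq: dict = field(default_factory=dict)  # continuous only

    @property
    def total(self) -> int:
        return sum(self.n.values())

    def to_json(self) -> str:
        def key(ab):
            return f"{ab[0]}{ab[1]}"

        payload = {
            "outcome_type": self.outcome_type.value,
            "n": {key(c): self.n[c] for c in CELLS},
        }
        if self.outcome_type is OutcomeType.BINARY:
            payload["events"] = {key(c): self.events[c] for c in CELLS}
        else:
            payload["sum"] = {key(c): self.sums[c] for c in CELLS}
            payload["sumsq"] = {key(c): self.sumsq[c] for c in CELLS}
        return json.dumps(payload, indent=2)


def read_trial_csv(path: Union[str, Path], outcome_type: OutcomeType) -> TrialDataset:
    """Read a trial dataset from CSV (comma-separated, header required, UTF-8).

    Columns are matched by name: ``z_a``, ``z_b``, ``y`` required, ``id``
    optional (auto-generated when absent).  Rows with a missing ``y`` are
    dropped and the dropped count is logged.
    """
    outcome_type = OutcomeType(outcome_type)
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str}, encoding="utf-8")
    missing = {"z_a", "z_b", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    n_missing = int(df["y"].isna().sum())
    if n_missing:
        logger.info("%s: dropped %d rows with missing outcome", path, n_missing)
        df = df[df["y"].notna()]
    return TrialDataset(df=df.reset_index(drop=True), outcome_type=outcome_type)


def write_trial_csv(data: TrialDataset, path: Union[str, Path]) -> None:
    """Write a trial dataset back to CSV; read -> write -> read round-trips."""
    data.df.to_csv(path, index=False)


def cross_tabulate(data: TrialDataset) -> CellCounts:
    """Summarise a dataset into per-cell counts (order-invariant).

    The four cell counts partition the dataset; cells with no records get
    ``n = 0``.
    """
    if len(data) == 0:
        raise ValueError("cannot cross-tabulate an empty dataset")
    counts = CellCounts(outcome_type=data.outcome_type)
    y = data.df["y"].to_numpy()
    for cell in CELLS:
        mask = data.cell_mask(*cell)
        counts.n[cell] = int(mask.sum())
        if data.outcome_type is OutcomeType.BINARY:
            counts.events[cell] = int(y[mask].sum())
        else:
            counts.sums[cell] = float(y[mask].sum())
            counts.sumsq[cell] = float((y[mask] ** 2).sum())
    return counts
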