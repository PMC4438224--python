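"""Discrete-time Markov cohort engine for post-delivery follow-up.

The delivery model hands a cohort over to a state-transition process for
long-term follow-up of mother and child.  This engine is deliberately
generic: states, per-cycle transition probabilities, per-state cycle costs,
cycle length and discount rate are all caller-supplied, with defaults of a
one-year cycle and no discounting.  Occupancy at cycle t is
``initial @ transition**t``; the cumulative cost is the discounted sum of
per-cycle state costs, with an optional half-cycle correction (off by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ROW_TOL = 1e-9


class MarkovValidationError(ValueError):
    pass


@dataclass
class MarkovModel:
    states: list[str]
    transition: np.ndarray  # (S, S) per-cycle probabilities
    cycle_cost: np.ndarray  # (S,) USD per state per cycle
    cycle_length: str = "year"
    discount_rate: float = 0.0  # per-cycle proportion

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.cycle_cost = np.asarray(self.cycle_cost, dtype=float)

    def validate(self) -> None:
        s = len(self.states)
        if self.transition.shape != (s, s):
            raise MarkovValidationError(
                f"transition matrix shape {self.transition.shape} != ({s}, {s})"
            )
        if self.cycle_cost.shape != (s,):
            raise MarkovValidationError("cycle_cost length must match states")
        if np.any(self.transition < 0) or np.any(self.transition > 1):
            raise MarkovValidationError("transition entries must lie in [0, 1]")
        rowsums = self.transition.sum(axis=1)
        bad = np.flatnonzero(np.abs(rowsums - 1.0) > ROW_TOL)
        if bad.size:
            raise MarkovValidationError(
                "transition rows do not sum to 1: "
                + ", ".join(f"{self.states[i]} (sum {rowsums[i]:g})" for i in bad)
            )
        if self.discount_rate < 0:
            raise MarkovValidationError("discount_rate must be >= 0")


@dataclass
class CohortTrace:
    """State occupancy per cycle plus discounted cumulative cost.

    ``occupancy`` has ``n_cycles + 1`` rows (cycle 0 = the initial
    distribution); costs accrue over cycles 0 … n_cycles − 1.
    """

    states: list[str]
    occupancy: np.ndarray  # (n_cycles + 1, S)
    cycle_costs: np.ndarray  # (n_cycles,) discounted USD per cycle
    discount_rate: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cumulative_cost_value(self) -> float:
        return float(self.cycle_costs.sum())


def run_cohort(
    model: MarkovModel,
    initial: Sequence[float],
    n_cycles: int,
    half_cycle_correction: bool = False,
) -> CohortTrace:
    """Propagate a cohort distribution through ``n_cycles`` transitions.

    ``initial`` must sum to 1.  With the half-cycle correction on, each
    cycle's cost uses the mean of its start and end occupancies.
    """
    model.validate()
    init = np.asarray(initial, dtype=float)
    if init.shape != (len(model.states),):
        raise MarkovValidationError("initial distribution length must match states")
    if np.any(init < 0) or abs(init.sum() - 1.0) > ROW_TOL:
        raise MarkovValidationError("initial distribution must be non-negative and sum to 1")
    if n_cycles < 0:
        raise MarkovValidationError("n_cycles must be >= 0")

    occupancy = np.empty((n_cycles + 1, len(model.states)))
    occupancy[0] = init
    for t in range(n_cycles):
        occupancy[t + 1] = occupancy[t] @ model.transition

    cycle_costs = np.zeros(n_cycles)
    for t in range(n_cycles):
        occ = (
            0.5 * (occupancy[t] + occupancy[t + 1])
            if half_cycle_correction
            else occupancy[t]
        )
        cycle_costs[t] = (occ @ model.cycle_cost) / (1.0 + model.discount_rate) ** t

    return CohortTrace(
        states=list(model.states),
        occupancy=occupancy,
        cycle_costs=cycle_costs,
        discount_rate=model.discount_rate,
    )


def cumulative_cost(trace: CohortTrace) -> float:
    """Discounted cumulative cost of a cohort trace (USD)."""
    return trace.cumulative_cost_value


def trace_frame(trace: CohortTrace) -> pd.DataFrame:
    """Occupancy trace as a DataFrame (cycles as rows, states as columns)."""
    df = pd.DataFrame(trace.occupancy, columns=trace.states)
    df.index.name = "cycle"
    return df
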