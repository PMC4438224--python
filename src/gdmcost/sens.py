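"""One-way deterministic sensitivity analysis (±20% by default).

Each scenario perturbs exactly one parameter by a signed proportion delta
and recomputes the per-case incremental cost and the annual budget impact:

* ``incidence`` — scales the condition incidence; per-case unchanged.
* ``condition_total_cost`` — scales the condition arm's total per-case
  cost; the reference (normal pregnancy) cost stays fixed.
* ``normal_pregnancy_cost`` — scales the routine cost in the reference arm
  only.
* ``child_complication_cost`` / ``mother_complication_cost`` — scale that
  component of the condition arm's breakdown.

Outputs can be ranked into tornado order by budget-impact range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .arms import CostBreakdown
from .budget import annual_cases, annual_pregnancies
from .params import ModelConfig

PARAMETERS = (
    "incidence",
    "condition_total_cost",
    "normal_pregnancy_cost",
    "child_complication_cost",
    "mother_complication_cost",
)

DEFAULT_DELTAS = (-0.20, 0.20)


@dataclass(frozen=True)
class SensitivityScenario:
    parameter: str
    delta: float  # signed proportion, e.g. ±0.20

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(
                f"unknown sensitivity parameter {self.parameter!r}; "
                f"expected one of {PARAMETERS}"
            )
        if self.delta <= -1.0:
            raise ValueError("delta must be greater than -1")


@dataclass(frozen=True)
class SensitivityRow:
    scenario: SensitivityScenario
    per_case: float
    bia: float


@dataclass
class SensitivityTable:
    base_per_case: float
    base_bia: float
    rows: list[SensitivityRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"parameter": "base", "delta": 0.0, "per_case_usd": self.base_per_case,
             "bia_usd": self.base_bia}
        ]
        records += [
            {
                "parameter": r.scenario.parameter,
                "delta": r.scenario.delta,
                "per_case_usd": r.per_case,
                "bia_usd": r.bia,
            }
            for r in self.rows
        ]
        return pd.DataFrame(records, columns=["parameter", "delta", "per_case_usd", "bia_usd"])


def apply_scenario(
    config: ModelConfig,
    condition: CostBreakdown,
    reference: CostBreakdown,
    scenario: SensitivityScenario,
) -> tuple[float, float]:
    """Evaluate one scenario; returns (per-case incremental USD, BIA USD)."""
    f = 1.0 + scenario.delta
    incidence = config.population.condition_incidence
    cond_total = condition.total
    ref_total = reference.total

    if scenario.parameter == "incidence":
        incidence *= f
    elif scenario.parameter == "condition_total_cost":
        cond_total *= f
    elif scenario.parameter == "normal_pregnancy_cost":
        ref_total *= f
    elif scenario.parameter == "child_complication_cost":
        cond_total = condition.mother + condition.child * f
    elif scenario.parameter == "mother_complication_cost":
        cond_total = condition.mother * f + condition.child

    per_case = cond_total - ref_total
    cases = annual_cases(annual_pregnancies(config.population), incidence)
    return per_case, cases * per_case


def run_table(
    config: ModelConfig,
    condition: CostBreakdown,
    reference: CostBreakdown,
    deltas: Sequence[float] = DEFAULT_DELTAS,
) -> SensitivityTable:
    """Full one-way table: one row per (parameter, delta), plus the base."""
    if not deltas:
        raise ValueError("deltas must be non-empty")
    base_per_case, base_bia = apply_scenario(
        config, condition, reference, SensitivityScenario("incidence", 0.0)
    )
    table = SensitivityTable(base_per_case=base_per_case, base_bia=base_bia)
    for parameter in PARAMETERS:
        for delta in sorted(deltas):
            scenario = SensitivityScenario(parameter, delta)
            per_case, bia = apply_scenario(config, condition, reference, scenario)
            table.rows.append(SensitivityRow(scenario, per_case, bia))
    return table


def tornado_order(table: SensitivityTable) -> list[str]:
    """Parameters ranked by descending |BIA(+δ) − BIA(−δ)|, ties alphabetical.

    Requires a symmetric delta set (every +δ paired with −δ).
    """
    by_param: dict[str, dict[float, float]] = {}
    for row in table.rows:
        by_param.setdefault(row.scenario.parameter, {})[row.scenario.delta] = row.bia

    ranges: dict[str, float] = {}
    for parameter, bias in by_param.items():
        pos = sorted(d for d in bias if d > 0)
        neg = sorted(-d for d in bias if d < 0)
        if pos != neg:
            raise ValueError(
                f"tornado ordering requires symmetric deltas; parameter "
                f"{parameter!r} has {sorted(bias)}"
            )
        ranges[parameter] = max(
            (abs(bias[d] - bias[-d]) for d in pos), default=0.0
        )
    return sorted(ranges, key=lambda p: (-ranges[p], p))
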