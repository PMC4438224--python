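"""Budget impact analysis: per-case incremental cost scaled to the
national annual burden via the pregnancy rate and condition incidence.

The chain is  population × rate/1000 → annual pregnancies;
× incidence → annual condition cases;  × per-case incremental cost →
annual budget impact.  Case counts stay real-valued internally and are
rounded (half away from zero) only for display.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import round_half_away
from .arms import Arm, CostBreakdown, incremental_cost, per_case_cost
from .params import ModelConfig, PopulationSpec


@dataclass(frozen=True)
class BudgetImpactResult:
    annual_pregnancies: float
    annual_cases: float
    per_case_incremental: float
    annual_budget_impact: float

    @property
    def annual_cases_display(self) -> int:
        return int(round_half_away(self.annual_cases))


def annual_pregnancies(pop: PopulationSpec) -> float:
    """National annual pregnancies = population × rate per 1,000 / 1,000."""
    return pop.population_size * pop.pregnancy_rate_per_1000 / 1000.0


def annual_cases(pregnancies: float, incidence: float) -> float:
    """Annual condition cases = pregnancies × incidence (real-valued)."""
    if not 0.0 <= incidence <= 1.0:
        raise ValueError(f"incidence must lie in [0, 1], got {incidence}")
    return pregnancies * incidence


def compute_budget_impact(
    config: ModelConfig,
    arm: Arm | CostBreakdown,
    reference: Arm | CostBreakdown,
    incidence: float | None = None,
) -> BudgetImpactResult:
    """National annual budget impact of the condition arm vs the reference.

    ``incidence`` overrides the population spec's condition incidence
    (used by sensitivity scenarios); all intermediate quantities are
    carried on the result.
    """
    pregnancies = annual_pregnancies(config.population)
    inc = config.population.condition_incidence if incidence is None else incidence
    cases = annual_cases(pregnancies, inc)
    per_case = incremental_cost(arm, reference)
    return BudgetImpactResult(
        annual_pregnancies=pregnancies,
        annual_cases=cases,
        per_case_incremental=per_case,
        annual_budget_impact=cases * per_case,
    )
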