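"""Typed parameter containers and readers: complication probability tables
per pregnancy arm, the unit-cost table, treatment-effect odds ratios,
delivery-strategy probabilities, and the population spec for budget impact.

The canonical complication vocabulary is the cost table's item names (e.g.
``Child_hyperbili``, ``Mother_pre eclampsia``); every probability entry must
reference one of them.  :data:`OUTCOME_ALIASES` documents how the source
studies' outcome labels map onto that vocabulary.  Percentages may be
written with a ``%`` suffix anywhere a proportion is expected.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Annotated, Literal, Optional

import yaml
from pydantic import (
    BaseModel,
    BeforeValidator,
    ConfigDict,
    Field,
    model_validator,
)

CONFIG_SCHEMA_VERSION = 1

ARM_NAMES = ("gdm_treated", "gdm_untreated", "obese", "non_obese", "normal")
STRATEGY_NAMES = ("elective_induction", "elective_cesarean", "expectant")

#: How outcome labels in the source studies map onto cost-table keys.
#: One alias table rather than per-table naming: the sources spell the same
#: outcome differently (``Birth weight >4000`` / ``Macrosomia``), and two
#: outcomes have no exactly-matching cost item (noted below).
OUTCOME_ALIASES: dict[str, str] = {
    "hypoglycemia": "Child_hypoglycemia",
    "hyperbilirubinemia": "Child_hyperbili",
    "birth weight >4000": "Child_macrosomia",
    "macrosomia": "Child_macrosomia",
    "preterm delivery": "Child_pretermdelivery",
    "NICU admission": "Child_NICU",
    "respiratory distress": "Child_resp_distress",
    "brachial plexus injury": "Child_brachplexus",
    "induction labor": "Mother_induction",
    "cesarean delivery": "Mother_cesarean",
    "shoulder dystocia": "Mother_shoulder",
    "preeclampsia": "Mother_pre eclampsia",
    "preeclampsia or gestational hypertension": "Mother_gesthyper",
    "hydramnion": "Mother_hydramnion",
    "stillbirth": "Mother_still birth",
    "anemia": "Mother_anemia",
    # insulin-treated / other diabetes in pregnancy: costed as GDM management
    "insulin-diabetes": "Mother_gdm",
    "other diabetes": "Mother_gest",
    "chronic hypertension": "Mother_hypertension",
    # eclampsia has no dedicated cost item; costed as pregnancy-induced
    # hypertension (the closest severe hypertensive-disorder item)
    "eclampsia": "Mother_PIH",
}


def _parse_proportion(v: object) -> object:
    if isinstance(v, str):
        s = v.strip()
        if s.endswith("%"):
            return float(s[:-1]) / 100.0
        return float(s)
    return v


Proportion = Annotated[
    float, BeforeValidator(_parse_proportion), Field(ge=0.0, le=1.0)
]


class ComplicationProbabilities(BaseModel):
    """Per-arm map of complication name → probability (proportion).

    ``significance`` stores the source study's statistical-significance
    flags as metadata; non-significant point estimates still enter the
    model unchanged.
    """

    model_config = ConfigDict(extra="forbid")

    arm: Optional[str] = None
    entries: dict[str, Proportion] = Field(default_factory=dict)
    significance: dict[str, Literal["S", "NS"]] = Field(default_factory=dict)


class CostTable(BaseModel):
    """Per-event USD costs plus the routine normal pregnancy/delivery cost."""

    model_config = ConfigDict(extra="forbid")

    entries: dict[str, Annotated[float, Field(ge=0)]]
    routine_normal_cost: Annotated[float, Field(ge=0)]


class OddsRatioRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    outcome: str
    comparison: str
    odds_ratio: Annotated[float, Field(gt=0)]
    ci_low: Annotated[float, Field(gt=0)]
    ci_high: Annotated[float, Field(gt=0)]
    source: str = ""

    @model_validator(mode="after")
    def _ci_brackets_point(self) -> "OddsRatioRecord":
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError(
                f"odds ratio {self.odds_ratio} outside its CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )
        return self


class StrategyProbabilities(BaseModel):
    """Outcome probabilities for one macrosomia delivery strategy."""

    model_config = ConfigDict(extra="forbid")

    strategy: Optional[str] = None
    entries: dict[str, Proportion] = Field(default_factory=dict)


class PopulationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    population_size: Annotated[float, Field(ge=0)]
    pregnancy_rate_per_1000: Annotated[float, Field(ge=0)]
    condition_incidence: Proportion


class CalibrationRow(BaseModel):
    """A published per-case cost breakdown pinned for calibrated mode."""

    model_config = ConfigDict(extra="forbid")

    mother: Annotated[float, Field(ge=0)]
    child: Annotated[float, Field(ge=0)]

    @property
    def total(self) -> float:
        return self.mother + self.child

    @model_validator(mode="after")
    def _positive_total(self) -> "CalibrationRow":
        if self.total <= 0:
            raise ValueError("calibration row must have a positive total")
        return self


class ModelOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: replacement shoulder-dystocia probability; None keeps the trial value
    shoulder_dystocia_override: Optional[Proportion] = None
    #: perinatal mortality probability; defaults to 0 (no published value)
    perinatal_mortality: Proportion = 0.0
    #: opt-in: derive treated-arm probabilities from odds ratios instead of
    #: the trial's treated arm (off to avoid double-counting the effect)
    apply_odds_ratios: bool = False
    #: conditional GDM incidence within the overweight arm (off by default)
    gdm_given_overweight: Optional[Proportion] = None


class ModelConfig(BaseModel):
    """The complete, validated parameter bundle for one model run."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = CONFIG_SCHEMA_VERSION
    cost_year: Optional[int] = None
    currency: str = "USD"
    population: PopulationSpec
    costs: CostTable
    probabilities: dict[str, ComplicationProbabilities]
    odds_ratios: list[OddsRatioRecord] = Field(default_factory=list)
    strategies: dict[str, StrategyProbabilities] = Field(default_factory=dict)
    calibration: Optional[dict[str, CalibrationRow]] = None
    options: ModelOptions = Field(default_factory=ModelOptions)

    @model_validator(mode="after")
    def _cross_checks(self) -> "ModelConfig":
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version} "
                f"(expected {CONFIG_SCHEMA_VERSION})"
            )
        for arm, probs in self.probabilities.items():
            if arm not in ARM_NAMES:
                raise ValueError(
                    f"unknown probability arm {arm!r}; expected one of {ARM_NAMES}"
                )
            probs.arm = arm
            unmatched = sorted(set(probs.entries) - set(self.costs.entries))
            if unmatched:
                raise ValueError(
                    f"arm {arm!r} references complications with no cost entry: "
                    + ", ".join(unmatched)
                )
            stray = sorted(set(probs.significance) - set(probs.entries))
            if stray:
                raise ValueError(
                    f"arm {arm!r} has significance flags for unknown entries: "
                    + ", ".join(stray)
                )
        for name, strat in self.strategies.items():
            if name not in STRATEGY_NAMES:
                raise ValueError(
                    f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}"
                )
            strat.strategy = name
        return self


def is_mother_item(name: str) -> bool:
    """Classify a cost-table key as maternal (else child-side)."""
    return name.startswith("Mother")


def load_config(path: str | Path) -> ModelConfig:
    """Read and fully validate a model configuration file (YAML/JSON)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ModelConfig.model_validate(doc)


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back out (proportions as plain numbers)."""
    doc = config.model_dump(exclude_none=False)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def builtin_pilot_parameters() -> ModelConfig:
    """The packaged 2011-USA pilot parameterization.

    Mild-GDM trial probabilities per treatment arm (plus the hydramnion
    0.6% / stillbirth 0.4% cohort add-ons), the obese/non-obese registry
    probabilities, the 2011 USD unit-cost table with its $7,790 routine
    normal-delivery cost, macrosomia odds ratios and delivery-strategy
    probabilities, USA demographics (population 313,847,500; 13.68
    pregnancies per 1,000; 5.5% GDM incidence), and the published per-case
    calibration breakdowns.
    """
    ref = resources.files("gdmcost.data").joinpath("us_2011_pilot.yaml")
    doc = yaml.safe_load(ref.read_text())
    return ModelConfig.model_validate(doc)


def or_to_probability(baseline: float, odds_ratio: float) -> float:
    """Convert a baseline risk and an odds ratio to the implied risk.

    odds = b / (1 - b); the odds ratio multiplies the odds, and the result
    is mapped back:  p = OR·b / (1 - b + OR·b).  Strictly increasing in
    both arguments and the identity at OR = 1.
    """
    if not 0.0 < baseline < 1.0:
        raise ValueError(f"baseline risk must lie strictly in (0, 1), got {baseline}")
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return odds_ratio * baseline / (1.0 - baseline + odds_ratio * baseline)
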