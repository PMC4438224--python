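"""Pregnancy arms: build normal / GDM / overweight cohorts as decision
trees and reduce them to per-case cost breakdowns.

Two arm modes ship:

* **calibrated** (default) — the tree is pinned to the published per-case
  mother/child breakdown for the arm, so downstream budget-impact numbers
  reproduce the published base case exactly.
* **mechanistic** — the tree is wired from the arm's complication
  probability table and the unit-cost table.  Complications are modeled as
  independent events whose expected costs add (per-case expected cost =
  routine cost + Σ p·c): the sources publish marginal probabilities only,
  and any tree wiring with the same marginals has the same expectation.

In both modes the routine normal pregnancy/delivery cost accrues on every
path and the arm evaluates through the generic tree engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .params import ComplicationProbabilities, CostTable, ModelConfig, is_mother_item
from .tree import (
    CostPair,
    DecisionTree,
    Edge,
    Node,
    ZERO_COST,
    chance,
    expected_value,
    terminal,
)

ARM_NAMES = ("normal", "gdm", "overweight")

#: which probability table feeds each arm; the GDM base case uses the
#: usual-care (untreated) trial arm — the conservative reading — and the
#: overweight arm the obese registry cohort
ARM_PROBABILITY_SOURCE = {
    "normal": "normal",
    "gdm": "gdm_untreated",
    "overweight": "obese",
}

ArmMode = Literal["calibrated", "mechanistic"]


@dataclass(frozen=True)
class CostBreakdown:
    """Per-case expected cost for one arm, split mother / child / total."""

    mother: float
    child: float

    @property
    def total(self) -> float:
        return self.mother + self.child


@dataclass
class Arm:
    name: str
    tree: DecisionTree
    mode: ArmMode


class UnknownArmError(ValueError):
    pass


def expected_complication_cost(
    probabilities: ComplicationProbabilities, costs: CostTable
) -> CostPair:
    """Expected complication cost Σ p·c, split into mother and child parts.

    Additive across events; raises with the full list of unmatched names if
    any complication lacks a cost entry.
    """
    unmatched = sorted(set(probabilities.entries) - set(costs.entries))
    if unmatched:
        raise KeyError(
            "complications without a cost entry: " + ", ".join(unmatched)
        )
    mother = child = 0.0
    for name, p in probabilities.entries.items():
        c = p * costs.entries[name]
        if is_mother_item(name):
            mother += c
        else:
            child += c
    return CostPair(mother, child)


def _event_chain(
    entries: list[tuple[str, float, CostPair]], tail: Node, tag: str
) -> Node:
    """Chain of chance nodes, one per complication.

    Each node branches into event (probability p, accruing the event cost)
    and no-event (probability 1−p); both branches rejoin at the next node,
    so the chain is linear in the number of events while still expanding to
    every complication combination as a distinct path.
    """
    node = tail
    for i in reversed(range(len(entries))):
        name, p, cost = entries[i]
        node = chance(
            [
                Edge(node, probability=p, cost=cost),
                Edge(node, probability=1.0 - p),
            ],
            label=name,
            node_id=f"{tag}:{name}",
        )
    return node


def _arm_entries(name: str, config: ModelConfig) -> list[tuple[str, float, CostPair]]:
    source = ARM_PROBABILITY_SOURCE[name]
    try:
        probs = config.probabilities[source]
    except KeyError:
        raise UnknownArmError(
            f"config lacks the {source!r} probability table required by arm {name!r}"
        ) from None
    unmatched = sorted(set(probs.entries) - set(config.costs.entries))
    if unmatched:
        raise KeyError("complications without a cost entry: " + ", ".join(unmatched))
    override = config.options.shoulder_dystocia_override
    out = []
    for item, p in probs.entries.items():
        if override is not None and item == "Mother_shoulder":
            p = override
        c = config.costs.entries[item]
        cost = CostPair(c, 0.0) if is_mother_item(item) else CostPair(0.0, c)
        out.append((item, p, cost))
    return out


def build_arm(name: str, config: ModelConfig, mode: ArmMode = "calibrated") -> Arm:
    """Construct one pregnancy arm as a valid decision tree.

    Calibrated mode requires a calibration row for the arm; mechanistic mode
    requires a complete probability→cost mapping.  The returned tree always
    accrues the routine normal-delivery cost on every path.
    """
    if name not in ARM_NAMES:
        raise UnknownArmError(f"unknown arm {name!r}; expected one of {ARM_NAMES}")
    routine = config.costs.routine_normal_cost

    if mode == "calibrated":
        if not config.calibration or name not in config.calibration:
            raise ValueError(
                f"calibrated mode requires a calibration entry for arm {name!r}"
            )
        row = config.calibration[name]
        # excess over the routine cost sits on the terminal payoff
        leaf = terminal(
            CostPair(row.mother - routine, row.child),
            label=f"{name} (calibrated)",
            node_id=f"{name}:leaf",
        )
        root = chance(
            [Edge(leaf, probability=1.0, cost=CostPair(routine, 0.0))],
            label=f"{name} pregnancy",
            node_id=f"{name}:root",
        )
        return Arm(name, DecisionTree(root, arm_name=name), "calibrated")

    if mode != "mechanistic":
        raise ValueError(f"unknown arm mode {mode!r}")

    entries = _arm_entries(name, config)
    tail = terminal(ZERO_COST, label="delivery complete", node_id=f"{name}:end")
    head = _event_chain(entries, tail, tag=name)

    q = config.options.gdm_given_overweight
    if name == "overweight" and q is not None:
        # nested GDM sub-branch: with conditional incidence q the cohort also
        # accrues the GDM complication chain before the obesity chain
        gdm_head = _event_chain(_arm_entries("gdm", config), head, tag=f"{name}+gdm")
        head = chance(
            [
                Edge(gdm_head, probability=q),
                Edge(head, probability=1.0 - q),
            ],
            label="GDM given overweight",
            node_id=f"{name}:gdm-split",
        )

    root = chance(
        [Edge(head, probability=1.0, cost=CostPair(routine, 0.0))],
        label=f"{name} pregnancy",
        node_id=f"{name}:root",
    )
    return Arm(name, DecisionTree(root, arm_name=name), "mechanistic")


def per_case_cost(arm: Arm) -> CostBreakdown:
    """Expected per-case cost of an arm, from tree rollback."""
    value = expected_value(arm.tree)
    return CostBreakdown(mother=value.mother, child=value.child)


def incremental_cost(arm: Arm | CostBreakdown, reference: Arm | CostBreakdown) -> float:
    """Total per-case cost difference, condition arm minus reference."""

    def total(x: Arm | CostBreakdown) -> float:
        return x.total if isinstance(x, CostBreakdown) else per_case_cost(x).total

    return total(arm) - total(reference)


def breakdown_frame(arms: Iterable[Arm]) -> pd.DataFrame:
    """Base-case table: one row per arm with mother / child / total USD."""
    rows = []
    for arm in arms:
        b = per_case_cost(arm)
        rows.append(
            {"arm": arm.name, "mother": b.mother, "child": b.child, "total": b.total}
        )
    return pd.DataFrame(rows, columns=["arm", "mother", "child", "total"])
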