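"""Decision-tree primitives: nodes, validation, expected-value rollback,
and an exhaustive path-enumeration oracle.

A tree is built from three node kinds:

* ``chance`` nodes, whose outgoing edges carry probabilities that must sum
  to one;
* ``decision`` nodes, whose edges carry no probability — evaluating a tree
  that contains them requires an explicit arm selection (the model never
  auto-optimises);
* ``terminal`` nodes, which carry a payoff.

Costs are two-component (:class:`CostPair`: mother / child, USD) and accrue
both on edges and on terminal payoffs; the value of a tree is the
probability-weighted sum of accumulated costs over all root-to-leaf paths,
computed by recursive rollback. :func:`enumerate_paths` recomputes the same
quantity by brute-force path enumeration and serves as an independent oracle
for the rollback.

Sharing of subtrees (DAG shape) is permitted — rollback is memoized — but
cycles are a validation violation.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import yaml

SCHEMA_VERSION = 1

#: absolute tolerance for chance-node probability sums and oracle agreement
PROB_TOL = 1e-9

#: refuse to enumerate trees with more root-to-leaf paths than this
MAX_PATHS = 10**6

NodeKind = Literal["decision", "chance", "terminal"]


class TreeError(ValueError):
    """Base class for decision-tree errors."""


class TreeStructureError(TreeError):
    """A serialized tree references a node it cannot resolve, or is
    otherwise structurally unparseable."""


class InvalidTreeError(TreeError):
    """Raised when an operation requires a valid tree but validation
    reported violations."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(
            "tree failed validation: " + "; ".join(str(i) for i in report.issues)
        )


class MissingSelectionError(TreeError):
    """A decision node was reached without an arm selection."""


class TreeSizeError(TreeError):
    """Path enumeration would exceed :data:`MAX_PATHS`."""


@dataclass(frozen=True)
class CostPair:
    """Two-component cost in USD, split the way the model reports it."""

    mother: float = 0.0
    child: float = 0.0

    @property
    def total(self) -> float:
        return self.mother + self.child

    def __add__(self, other: "CostPair") -> "CostPair":
        return CostPair(self.mother + other.mother, self.child + other.child)

    def scaled(self, k: float) -> "CostPair":
        return CostPair(self.mother * k, self.child * k)

    def isclose(self, other: "CostPair", tol: float = PROB_TOL) -> bool:
        return (
            abs(self.mother - other.mother) <= tol
            and abs(self.child - other.child) <= tol
        )


ZERO_COST = CostPair(0.0, 0.0)


@dataclass
class Edge:
    """A branch out of a node.

    ``probability`` is required (a proportion) for chance-node children and
    must be ``None`` for decision-node children.  ``cost`` is the
    incremental cost accrued when the cohort traverses this branch.
    """

    child: "Node"
    probability: float | None = None
    cost: CostPair = ZERO_COST


@dataclass
class Node:
    node_id: str
    kind: NodeKind
    label: str = ""
    children: list[Edge] = field(default_factory=list)
    payoff: CostPair | None = None


@dataclass
class DecisionTree:
    root: Node
    arm_name: str = ""


# -- constructors -----------------------------------------------------------

_id_counter = itertools.count()


def _auto_id() -> str:
    return f"n{next(_id_counter)}"


def terminal(payoff: CostPair = ZERO_COST, label: str = "", node_id: str | None = None) -> Node:
    return Node(node_id or _auto_id(), "terminal", label, payoff=payoff)


def chance(edges: Sequence[Edge], label: str = "", node_id: str | None = None) -> Node:
    return Node(node_id or _auto_id(), "chance", label, children=list(edges))


def decision(edges: Sequence[Edge], label: str = "", node_id: str | None = None) -> Node:
    return Node(node_id or _auto_id(), "decision", label, children=list(edges))


# -- validation -------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    node_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.node_id}] {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.issues

    def add(self, node_id: str, message: str) -> None:
        self.issues.append(ValidationIssue(node_id, message))


def _finite_nonneg(c: CostPair) -> bool:
    return (
        math.isfinite(c.mother)
        and math.isfinite(c.child)
        and c.mother >= 0
        and c.child >= 0
    )


def validate_tree(tree: DecisionTree) -> ValidationReport:
    """Check every structural invariant and report all violations.

    Violations are reported, never raised; an empty report means the tree is
    valid.  Checks: node-id uniqueness, terminal payoffs, child counts,
    probability presence/range/sums (tolerance :data:`PROB_TOL`),
    non-negative finite costs, and acyclicity.
    """
    report = ValidationReport()
    seen_ids: dict[str, int] = {}
    done: set[int] = set()  # fully-explored nodes, by object identity
    on_path: set[int] = set()

    def visit(node: Node) -> None:
        oid = id(node)
        if oid in on_path:
            report.add(node.node_id, "cycle detected through this node")
            return
        if oid in done:
            return  # shared subtree: already checked
        n_prev = seen_ids.get(node.node_id)
        if n_prev is not None and n_prev != oid:
            report.add(node.node_id, "duplicate node_id")
        seen_ids[node.node_id] = oid

        if node.kind == "terminal":
            if node.children:
                report.add(node.node_id, "terminal node has children")
            if node.payoff is None:
                report.add(node.node_id, "terminal node lacks a payoff")
            elif not _finite_nonneg(node.payoff):
                report.add(node.node_id, "payoff must be finite and non-negative")
        elif node.kind in ("chance", "decision"):
            if node.payoff is not None:
                report.add(node.node_id, f"{node.kind} node carries a payoff")
            if not node.children:
                report.add(node.node_id, f"{node.kind} node has no children (non-terminal leaf)")
        else:
            report.add(node.node_id, f"unknown node kind {node.kind!r}")
            return

        if node.kind == "chance":
            total = 0.0
            complete = True
            for edge in node.children:
                if edge.probability is None:
                    report.add(node.node_id, "chance-node branch lacks a probability")
                    complete = False
                elif not (0.0 <= edge.probability <= 1.0) or not math.isfinite(edge.probability):
                    report.add(
                        node.node_id,
                        f"branch probability {edge.probability} outside [0, 1]",
                    )
                    complete = False
                else:
                    total += edge.probability
            if complete and node.children and abs(total - 1.0) > PROB_TOL:
                report.add(node.node_id, f"probabilities sum to {total:g} ≠ 1")
        elif node.kind == "decision":
            for edge in node.children:
                if edge.probability is not None:
                    report.add(node.node_id, "decision-node branch carries a probability")

        for edge in node.children:
            if not _finite_nonneg(edge.cost):
                report.add(node.node_id, "edge cost must be finite and non-negative")
            on_path.add(oid)
            visit(edge.child)
            on_path.discard(oid)
        done.add(oid)

    visit(tree.root)
    return report


# -- evaluation -------------------------------------------------------------

Selection = Mapping[str, int | str]


def _select_edge(node: Node, selections: Selection | None) -> Edge:
    if not selections or node.node_id not in selections:
        raise MissingSelectionError(
            f"decision node {node.node_id!r} ({node.label!r}) requires an "
            "explicit arm selection; automatic optimisation is not performed"
        )
    sel = selections[node.node_id]
    if isinstance(sel, int):
        try:
            return node.children[sel]
        except IndexError:
            raise MissingSelectionError(
                f"selection index {sel} out of range at node {node.node_id!r}"
            ) from None
    for edge in node.children:
        if edge.child.label == sel:
            return edge
    raise MissingSelectionError(
        f"no child labelled {sel!r} at decision node {node.node_id!r}"
    )


def expected_value(
    tree: DecisionTree,
    selections: Selection | None = None,
    validate: bool = True,
) -> CostPair:
    """Roll the tree back to its expected accumulated cost.

    Chance nodes contribute the probability-weighted sum of their branches;
    decision nodes contribute the branch named in ``selections``
    (``node_id`` → child index or child label).  Edge costs and terminal
    payoffs are summed along each path.

    Raises :class:`InvalidTreeError` if ``validate`` is on and the tree
    violates any invariant (e.g. a probability-sum violation).
    """
    if validate:
        report = validate_tree(tree)
        if not report.valid:
            raise InvalidTreeError(report)

    memo: dict[int, CostPair] = {}

    def value(node: Node) -> CostPair:
        oid = id(node)
        if oid in memo:
            return memo[oid]
        if node.kind == "terminal":
            out = node.payoff if node.payoff is not None else ZERO_COST
        elif node.kind == "chance":
            out = ZERO_COST
            for edge in node.children:
                out = out + (edge.cost + value(edge.child)).scaled(edge.probability)
        else:  # decision
            edge = _select_edge(node, selections)
            out = edge.cost + value(edge.child)
        memo[oid] = out
        return out

    return value(tree.root)


@dataclass(frozen=True)
class PathRecord:
    """One root-to-leaf path: labels, joint probability, accumulated cost."""

    node_labels: tuple[str, ...]
    joint_probability: float
    accumulated_cost: CostPair


def enumerate_paths(
    tree: DecisionTree,
    selections: Selection | None = None,
    validate: bool = True,
) -> list[PathRecord]:
    """Exhaustively enumerate root-to-leaf paths (the rollback oracle).

    The joint probability of a path is the product of its edge
    probabilities; summed over all paths it is 1, and the
    probability-weighted sum of accumulated costs equals
    :func:`expected_value`, both to within :data:`PROB_TOL`.

    Raises :class:`TreeSizeError` beyond :data:`MAX_PATHS` paths.
    """
    if validate:
        report = validate_tree(tree)
        if not report.valid:
            raise InvalidTreeError(report)

    records: list[PathRecord] = []

    def walk(node: Node, labels: tuple[str, ...], prob: float, cost: CostPair) -> None:
        labels = labels + (node.label or node.node_id,)
        if node.kind == "terminal":
            if len(records) >= MAX_PATHS:
                raise TreeSizeError(
                    f"tree has more than {MAX_PATHS} root-to-leaf paths"
                )
            payoff = node.payoff if node.payoff is not None else ZERO_COST
            records.append(PathRecord(labels, prob, cost + payoff))
            return
        if node.kind == "decision":
            edge = _select_edge(node, selections)
            walk(edge.child, labels, prob, cost + edge.cost)
            return
        for edge in node.children:
            walk(edge.child, labels, prob * edge.probability, cost + edge.cost)

    walk(tree.root, (), 1.0, ZERO_COST)
    return records


def scale_costs(tree: DecisionTree, k: float) -> DecisionTree:
    """Return a copy of the tree with every edge cost and payoff scaled by k."""
    copies: dict[int, Node] = {}

    def copy(node: Node) -> Node:
        oid = id(node)
        if oid in copies:
            return copies[oid]
        out = Node(
            node.node_id,
            node.kind,
            node.label,
            payoff=node.payoff.scaled(k) if node.payoff is not None else None,
        )
        copies[oid] = out
        out.children = [
            Edge(copy(e.child), e.probability, e.cost.scaled(k)) for e in node.children
        ]
        return out

    return DecisionTree(copy(tree.root), tree.arm_name)


# -- random fixture generator ----------------------------------------------


def random_tree(seed: int, max_depth: int = 4, max_branching: int = 3) -> DecisionTree:
    """Generate a random valid chance tree, deterministically from ``seed``.

    Branch probabilities are drawn uniformly and normalised to sum to one;
    edge costs and terminal payoffs are drawn non-negative.  Used as a
    fixture source for oracle testing.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if max_branching < 2:
        raise ValueError("max_branching must be >= 2")
    rng = np.random.default_rng(seed)
    counter = itertools.count()

    def build(depth: int) -> Node:
        nid = f"r{next(counter)}"
        if depth >= max_depth or (depth > 0 and rng.random() < 0.3):
            payoff = CostPair(float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)))
            return Node(nid, "terminal", f"leaf-{nid}", payoff=payoff)
        k = int(rng.integers(2, max_branching + 1))
        raw = rng.uniform(0.05, 1.0, size=k)
        probs = raw / raw.sum()
        probs[-1] = 1.0 - probs[:-1].sum()
        edges = [
            Edge(
                build(depth + 1),
                probability=float(p),
                cost=CostPair(float(rng.uniform(0, 100)), float(rng.uniform(0, 100))),
            )
            for p in probs
        ]
        return Node(nid, "chance", f"chance-{nid}", children=edges)

    return DecisionTree(build(0), arm_name=f"random-{seed}")


# -- serialization ----------------------------------------------------------
#
# Schema (version 1): a mapping with "schema_version", "arm_name" and "root".
# Each node is {"id", "kind", "label", ...}; terminals carry
# "payoff": {"mother", "child"}; other nodes carry "children", a list of
# {"p": number | "complement", "cost_mother", "cost_child", "node": <node>}.
# "p" is omitted for decision-node children.  At most one branch of a chance
# node may declare "p": "complement"; it resolves at load time to one minus
# the sum of its siblings (the parameter tables list event probabilities
# only, never the residual no-event branch).


def tree_to_dict(tree: DecisionTree) -> dict:
    def encode(node: Node) -> dict:
        out: dict = {"id": node.node_id, "kind": node.kind, "label": node.label}
        if node.kind == "terminal":
            payoff = node.payoff if node.payoff is not None else ZERO_COST
            out["payoff"] = {"mother": payoff.mother, "child": payoff.child}
        else:
            out["children"] = [
                {
                    **({"p": e.probability} if e.probability is not None else {}),
                    "cost_mother": e.cost.mother,
                    "cost_child": e.cost.child,
                    "node": encode(e.child),
                }
                for e in node.children
            ]
        return out

    return {
        "schema_version": SCHEMA_VERSION,
        "arm_name": tree.arm_name,
        "root": encode(tree.root),
    }


def tree_from_dict(doc: Mapping) -> DecisionTree:
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise TreeStructureError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    if "root" not in doc:
        raise TreeStructureError("document lacks a 'root' node")

    def decode(obj, parent_id: str) -> Node:
        if not isinstance(obj, Mapping):
            raise TreeStructureError(
                f"malformed node reference under node {parent_id!r}"
            )
        nid = str(obj.get("id") or _auto_id())
        kind = obj.get("kind")
        if kind not in ("decision", "chance", "terminal"):
            raise TreeStructureError(f"node {nid!r} has unknown kind {kind!r}")
        label = str(obj.get("label", ""))
        if kind == "terminal":
            payoff = obj.get("payoff", {})
            return Node(
                nid,
                "terminal",
                label,
                payoff=CostPair(
                    float(payoff.get("mother", 0.0)), float(payoff.get("child", 0.0))
                ),
            )
        edges: list[Edge] = []
        complement_at: int | None = None
        prob_sum = 0.0
        for i, child_obj in enumerate(obj.get("children", [])):
            if "node" not in child_obj:
                raise TreeStructureError(f"branch {i} of node {nid!r} lacks a 'node'")
            p = child_obj.get("p")
            if p == "complement":
                if complement_at is not None:
                    raise TreeStructureError(
                        f"node {nid!r} declares more than one complement branch"
                    )
                complement_at = i
                prob = None
            elif p is None:
                prob = None
            else:
                prob = float(p)
                prob_sum += prob
            edges.append(
                Edge(
                    decode(child_obj["node"], nid),
                    probability=prob,
                    cost=CostPair(
                        float(child_obj.get("cost_mother", 0.0)),
                        float(child_obj.get("cost_child", 0.0)),
                    ),
                )
            )
        if complement_at is not None:
            residual = 1.0 - prob_sum
            if residual < -PROB_TOL:
                raise TreeStructureError(
                    f"complement branch of node {nid!r} would be negative "
                    f"({residual:g})"
                )
            edges[complement_at].probability = max(residual, 0.0)
        return Node(nid, kind, label, children=edges)

    return DecisionTree(decode(doc["root"], "<root>"), str(doc.get("arm_name", "")))


def save_tree(tree: DecisionTree, path: str | Path) -> None:
    path = Path(path)
    doc = tree_to_dict(tree)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def load_tree(path: str | Path) -> DecisionTree:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return tree_from_dict(doc)
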