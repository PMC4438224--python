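"""Decision-tree engine: validation, rollback, enumeration oracle,
random-tree generator, serialization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdmcost.tree import (
    CostPair,
    DecisionTree,
    Edge,
    InvalidTreeError,
    MissingSelectionError,
    Node,
    TreeSizeError,
    TreeStructureError,
    chance,
    decision,
    enumerate_paths,
    expected_value,
    load_tree,
    random_tree,
    save_tree,
    scale_costs,
    terminal,
    tree_from_dict,
    tree_to_dict,
    validate_tree,
)


def two_leaf_chance(p0, p1, c0=(10, 0), c1=(0, 0)):
    return DecisionTree(
        chance(
            [
                Edge(terminal(CostPair(*c0)), probability=p0),
                Edge(terminal(CostPair(*c1)), probability=p1),
            ]
        )
    )


def depth2_binary():
    """2x2 symmetric tree with leaf mother costs 0, 1, 2, 3."""
    leaves = [terminal(CostPair(float(i), 0.0)) for i in range(4)]
    lower = [
        chance([Edge(leaves[0], probability=0.5), Edge(leaves[1], probability=0.5)]),
        chance([Edge(leaves[2], probability=0.5), Edge(leaves[3], probability=0.5)]),
    ]
    return DecisionTree(
        chance([Edge(lower[0], probability=0.5), Edge(lower[1], probability=0.5)])
    )


class TestValidation:
    def test_symmetric_chance_node_is_valid(self):
        assert validate_tree(two_leaf_chance(0.5, 0.5)).valid

    def test_probability_sum_violation_is_reported_with_the_sum(self):
        report = validate_tree(two_leaf_chance(0.6, 0.6))
        assert not report.valid
        assert any("sum to 1.2" in issue.message for issue in report.issues)

    def test_all_violations_reported_not_raised(self):
        bad_terminal = Node("t", "terminal", payoff=None)
        tree = DecisionTree(
            chance(
                [
                    Edge(bad_terminal, probability=0.7),
                    Edge(terminal(CostPair(-5.0, 0.0)), probability=0.7),
                ],
                node_id="c",
            )
        )
        report = validate_tree(tree)
        messages = [i.message for i in report.issues]
        assert any("sum to 1.4" in m for m in messages)
        assert any("payoff" in m for m in messages)
        assert any("non-negative" in m for m in messages)

    def test_nonterminal_leaf_and_decision_probability_flagged(self):
        empty_chance = Node("e", "chance")
        tree = DecisionTree(decision([Edge(empty_chance, probability=0.3)], node_id="d"))
        report = validate_tree(tree)
        messages = [i.message for i in report.issues]
        assert any("no children" in m for m in messages)
        assert any("decision-node branch carries a probability" in m for m in messages)

    def test_cycle_detected(self):
        a = Node("a", "chance")
        b = Node("b", "chance")
        a.children = [Edge(b, probability=1.0)]
        b.children = [Edge(a, probability=1.0)]
        report = validate_tree(DecisionTree(a))
        assert any("cycle" in i.message for i in report.issues)

    def test_duplicate_node_id_flagged(self):
        tree = DecisionTree(
            chance(
                [
                    Edge(terminal(CostPair(), node_id="dup"), probability=0.5),
                    Edge(terminal(CostPair(), node_id="dup"), probability=0.5),
                ]
            )
        )
        assert any("duplicate" in i.message for i in validate_tree(tree).issues)

    def test_shared_subtree_is_acyclic_and_valid(self):
        shared = terminal(CostPair(5.0, 0.0))
        tree = DecisionTree(
            chance([Edge(shared, probability=0.4), Edge(shared, probability=0.6)])
        )
        assert validate_tree(tree).valid

    def test_complement_branch_resolved_at_parse_time(self):
        # event probabilities from the elective-induction strategy
        # (cesarean shoulder dystocia 0.3%, vaginal 14.5%); residual 85.2%
        doc = {
            "schema_version": 1,
            "root": {
                "kind": "chance",
                "label": "delivery",
                "children": [
                    {"p": 0.003, "node": {"kind": "terminal", "payoff": {}}},
                    {"p": 0.145, "node": {"kind": "terminal", "payoff": {}}},
                    {"p": "complement", "node": {"kind": "terminal", "payoff": {}}},
                ],
            },
        }
        tree = tree_from_dict(doc)
        assert validate_tree(tree).valid
        assert tree.root.children[2].probability == pytest.approx(0.852, abs=1e-12)


class TestExpectedValue:
    def test_single_terminal_routine_cost(self):
        tree = DecisionTree(terminal(CostPair(7790.0, 0.0)))
        assert expected_value(tree) == CostPair(7790.0, 0.0)

    def test_probability_weighting(self):
        assert expected_value(two_leaf_chance(0.3, 0.7)).mother == pytest.approx(3.0)

    def test_depth2_binary_matches_brute_force(self):
        # four equiprobable paths with mother costs 0..3 -> mean 1.5
        expected = sum(0.25 * c for c in (0.0, 1.0, 2.0, 3.0))
        assert expected_value(depth2_binary()).mother == pytest.approx(expected)

    def test_refuses_invalid_tree(self):
        with pytest.raises(InvalidTreeError):
            expected_value(two_leaf_chance(0.6, 0.6))

    def test_edge_costs_accrue_along_paths(self):
        leaf = terminal(CostPair(100.0, 50.0))
        tree = DecisionTree(
            chance([Edge(leaf, probability=1.0, cost=CostPair(10.0, 20.0))])
        )
        assert expected_value(tree) == CostPair(110.0, 70.0)

    def test_decision_node_requires_explicit_selection(self):
        tree = DecisionTree(
            decision(
                [
                    Edge(terminal(CostPair(10.0, 0.0), label="induce")),
                    Edge(terminal(CostPair(30.0, 0.0), label="cesarean")),
                ],
                node_id="strategy",
            )
        )
        with pytest.raises(MissingSelectionError):
            expected_value(tree)
        by_label = expected_value(tree, selections={"strategy": "cesarean"})
        by_index = expected_value(tree, selections={"strategy": 1})
        assert by_label == by_index == CostPair(30.0, 0.0)


class TestEnumeratePaths:
    def test_single_terminal_single_path(self):
        paths = enumerate_paths(DecisionTree(terminal(CostPair(1.0, 2.0))))
        assert len(paths) == 1
        assert paths[0].joint_probability == 1.0
        assert paths[0].accumulated_cost == CostPair(1.0, 2.0)

    def test_depth2_binary_product_rule(self):
        paths = enumerate_paths(depth2_binary())
        assert sorted(p.joint_probability for p in paths) == [0.25] * 4

    def test_size_guard(self, monkeypatch):
        monkeypatch.setattr("gdmcost.tree.MAX_PATHS", 3)
        with pytest.raises(TreeSizeError):
            enumerate_paths(depth2_binary())

    def test_decision_selection_restricts_paths(self):
        tree = DecisionTree(
            decision(
                [Edge(depth2_binary().root), Edge(terminal(CostPair(), label="t"))],
                node_id="d",
            )
        )
        assert len(enumerate_paths(tree, selections={"d": 0})) == 4


class TestRandomTrees:
    def test_minimal_case_is_a_two_leaf_chance_tree(self):
        tree = random_tree(seed=1, max_depth=1, max_branching=2)
        assert tree.root.kind == "chance"
        assert len(tree.root.children) == 2
        assert all(e.child.kind == "terminal" for e in tree.root.children)

    def test_deterministic_given_seed(self):
        assert tree_to_dict(random_tree(7, 4, 3)) == tree_to_dict(random_tree(7, 4, 3))

    @pytest.mark.parametrize("seed", [0, 7, 42, 123])
    def test_generated_trees_pass_validation(self, seed):
        assert validate_tree(random_tree(seed, max_depth=4, max_branching=3)).valid

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            random_tree(0, max_depth=0)
        with pytest.raises(ValueError):
            random_tree(0, max_depth=2, max_branching=1)


class TestProperties:
    @pytest.mark.parametrize("seed", range(40))
    def test_rollback_agrees_with_path_enumeration_oracle(self, seed):
        tree = random_tree(seed, max_depth=5, max_branching=4)
        paths = enumerate_paths(tree)
        assert math.fsum(p.joint_probability for p in paths) == pytest.approx(1.0, abs=1e-9)
        mother = math.fsum(p.joint_probability * p.accumulated_cost.mother for p in paths)
        child = math.fsum(p.joint_probability * p.accumulated_cost.child for p in paths)
        value = expected_value(tree)
        assert value.mother == pytest.approx(mother, abs=1e-9)
        assert value.child == pytest.approx(child, abs=1e-9)

    def test_cost_scaling_linearity(self):
        tree = random_tree(11, max_depth=4, max_branching=3)
        base = expected_value(tree)
        doubled = expected_value(scale_costs(tree, 2.0))
        assert doubled.mother == base.mother * 2.0  # power of two: exact
        assert doubled.child == base.child * 2.0
        scaled = expected_value(scale_costs(tree, 3.7))
        assert scaled.mother == pytest.approx(base.mother * 3.7, rel=1e-12)

    def test_zero_probability_branch_is_neutral(self):
        tree = two_leaf_chance(0.3, 0.7)
        base = expected_value(tree)
        tree.root.children.append(
            Edge(terminal(CostPair(1e6, 1e6)), probability=0.0)
        )
        assert validate_tree(tree).valid
        assert expected_value(tree).isclose(base, tol=1e-9)

    def test_splitting_a_branch_in_half_is_neutral(self):
        tree = two_leaf_chance(0.3, 0.7)
        base = expected_value(tree)
        edge = tree.root.children[0]
        half = Edge(edge.child, probability=edge.probability / 2, cost=edge.cost)
        edge.probability /= 2
        tree.root.children.insert(1, half)
        assert validate_tree(tree).valid
        assert expected_value(tree).isclose(base, tol=1e-9)


    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        costs=st.lists(st.floats(0.0, 1e6), min_size=2, max_size=6),
        weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    )
    def test_expected_value_is_a_convex_combination_of_leaves(self, costs, weights):
        k = min(len(costs), len(weights))
        costs, weights = costs[:k], weights[:k]
        total = math.fsum(weights)
        probs = [w / total for w in weights]
        probs[-1] = 1.0 - math.fsum(probs[:-1])
        tree = DecisionTree(
            chance(
                [
                    Edge(terminal(CostPair(c, 0.0)), probability=p)
                    for c, p in zip(costs, probs)
                ]
            )
        )
        value = expected_value(tree).mother
        assert min(costs) - 1e-6 <= value <= max(costs) + 1e-6


class TestSerialization:
    def test_round_trip_preserves_structure(self, tmp_path):
        tree = random_tree(3, max_depth=3, max_branching=3)
        doc = tree_to_dict(tree)
        assert doc["schema_version"] == 1
        assert tree_to_dict(tree_from_dict(doc)) == doc
        for name in ("t.yaml", "t.json"):
            save_tree(tree, tmp_path / name)
            assert tree_to_dict(load_tree(tmp_path / name)) == doc

    def test_structural_errors_name_the_offender(self):
        with pytest.raises(TreeStructureError, match="schema_version"):
            tree_from_dict({"schema_version": 99, "root": {}})
        with pytest.raises(TreeStructureError, match="'root'"):
            tree_from_dict({"schema_version": 1})
        with pytest.raises(TreeStructureError, match="badkind"):
            tree_from_dict(
                {"schema_version": 1, "root": {"kind": "badkind", "id": "badkind"}}
            )
        with pytest.raises(TreeStructureError, match="lacks a 'node'"):
            tree_from_dict(
                {"schema_version": 1,
                 "root": {"kind": "chance", "id": "c", "children": [{"p": 1.0}]}}
            )
        with pytest.raises(TreeStructureError, match="complement"):
            tree_from_dict(
                {"schema_version": 1,
                 "root": {"kind": "chance", "id": "c", "children": [
                     {"p": 0.8, "node": {"kind": "terminal", "payoff": {}}},
                     {"p": "complement", "node": {"kind": "terminal", "payoff": {}}},
                     {"p": "complement", "node": {"kind": "terminal", "payoff": {}}},
                 ]}}
            )
        with pytest.raises(TreeStructureError, match="negative"):
            tree_from_dict(
                {"schema_version": 1,
                 "root": {"kind": "chance", "id": "c", "children": [
                     {"p": 1.2, "node": {"kind": "terminal", "payoff": {}}},
                     {"p": "complement", "node": {"kind": "terminal", "payoff": {}}},
                 ]}}
            )
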