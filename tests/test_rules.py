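"""Rule compilation, interval arithmetic, serialisation round trips, and the
tree-vs-rules semantic equivalence oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlapipe.kb import kb1_source_tree, kb2_source_tree
from xlapipe.rules import (
    Condition,
    Rule,
    RuleSet,
    check_partition,
    compile_rules,
    parse_rules,
    serialize_rules,
)
from xlapipe.trees import DecisionTree, Internal, Leaf, predict


def _random_records(tree, n, seed):
    rng = np.random.default_rng(seed)
    attrs = tree.attributes
    return [
        dict(zip(attrs, vals))
        for vals in rng.uniform(-10.0, 200.0, size=(n, len(attrs)))
    ]


def _grid_records(tree):
    """Exhaustive grid over the threshold-induced cells of a tree's space."""
    cuts: dict[str, set] = {a: set() for a in tree.attributes}

    def walk(node):
        if isinstance(node, Internal):
            cuts[node.attribute].add(node.threshold)
            walk(node.left)
            walk(node.right)

    walk(tree.root)
    import itertools

    axes = []
    for attr in tree.attributes:
        edges = sorted(cuts[attr])
        probes = [edges[0] - 1.0] if edges else [0.0]
        probes += [(a + b) / 2 for a, b in zip(edges[:-1], edges[1:])]
        probes += edges  # boundary points: ties must resolve identically
        axes.append(probes)
    return [dict(zip(tree.attributes, combo)) for combo in itertools.product(*axes)]


def assert_tree_rules_equivalent(tree, n_random=10_000, seed=0):
    """The compiled ruleset must reproduce the tree everywhere: on the full
    threshold grid and on randomly drawn records."""
    from xlapipe.engine import run

    ruleset = compile_rules(tree)
    assert ruleset.exhaustive and ruleset.mutually_exclusive
    for record in _grid_records(tree) + _random_records(tree, n_random, seed):
        assert run(ruleset, record).conclusion == predict(tree, record)


class TestCompileRules:
    def test_course_knowledge_tree_compiles_to_seven_rules(self):
        ruleset = compile_rules(kb1_source_tree())
        assert len(ruleset.rules) == 7
        assert ruleset.exhaustive and ruleset.mutually_exclusive

    def test_single_leaf_tree_gives_one_unconditional_rule(self):
        tree = DecisionTree(Leaf("severe", {"severe": 5}), "y", ("severe",), ())
        ruleset = compile_rules(tree)
        assert len(ruleset.rules) == 1
        assert ruleset.rules[0].conditions == ()
        assert ruleset.exhaustive and ruleset.mutually_exclusive

    def test_complete_depth2_tree_gives_four_exclusive_rules(self):
        tree = DecisionTree(
            Internal(
                "a",
                0.0,
                Internal("b", 0.0, Leaf("w", {}), Leaf("x", {}), {}),
                Internal("b", 0.0, Leaf("y", {}), Leaf("z", {}), {}),
                {},
            ),
            "y",
            ("w", "x", "y", "z"),
            ("a", "b"),
        )
        ruleset = compile_rules(tree)
        assert len(ruleset.rules) == 4
        assert ruleset.mutually_exclusive and ruleset.exhaustive

    def test_same_attribute_conditions_merge_to_one_interval(self):
        ruleset = compile_rules(kb1_source_tree())
        # the mid-IgA rule passes through two IgA splits; they must merge
        mid = next(r for r in ruleset.rules if any(c.op == "interval" for c in r.conditions))
        intervals = [c for c in mid.conditions if c.op == "interval"]
        assert len(intervals) == 1
        assert intervals[0].attribute == "iga_pct"
        assert intervals[0].bound == (20.0, 50.0)

    @pytest.mark.parametrize("tree_factory", [kb1_source_tree, kb2_source_tree])
    def test_rule_count_equals_leaf_count(self, tree_factory):
        tree = tree_factory()
        assert len(compile_rules(tree).rules) == tree.n_leaves()

    def test_semantic_equivalence_with_source_trees(self):
        assert_tree_rules_equivalent(kb1_source_tree(), n_random=2000, seed=1)
        assert_tree_rules_equivalent(kb2_source_tree(), n_random=2000, seed=2)


class TestConditionsAndRules:
    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            Condition("iga_pct", "interval", (50.0, 20.0))

    def test_contradictory_conditions_rejected(self):
        with pytest.raises(ValueError, match="empty intersection"):
            Rule(
                "bad",
                (Condition("x", "lt", 10.0), Condition("x", "ge", 20.0)),
                "severe",
            )

    def test_interval_membership_is_closed_open(self):
        cond = Condition("iga_pct", "interval", (20.0, 50.0))
        assert cond.holds(20.0) and cond.holds(49.999)
        assert not cond.holds(50.0) and not cond.holds(19.999)


class TestSerialisation:
    def test_json_round_trip_is_a_fixed_point(self, kb1):
        text = serialize_rules(kb1, "json")
        again = serialize_rules(parse_rules(text, "json"), "json")
        assert text == again

    def test_clips_export_has_one_defrule_per_rule(self, kb1):
        text = serialize_rules(kb1, "clips")
        assert text.count("(defrule") == 7

    def test_clips_round_trip_preserves_semantics(self, kb1):
        parsed = parse_rules(serialize_rules(kb1, "clips"), "clips")
        assert len(parsed.rules) == len(kb1.rules)
        for original, round_tripped in zip(kb1.rules, parsed.rules):
            assert round_tripped.conclusion == original.conclusion
            assert round_tripped.conditions == original.conditions

    def test_empty_ruleset_serialises_validly(self):
        empty = RuleSet([])
        assert parse_rules(serialize_rules(empty, "json"), "json").rules == []
        assert serialize_rules(empty, "clips") == ""

    def test_unknown_dialect_is_an_error(self, kb1):
        with pytest.raises(ValueError, match="dialect"):
            serialize_rules(kb1, "prolog")

    def test_json_syntax_error_reports_line(self):
        with pytest.raises(ValueError, match="line"):
            parse_rules('{"rules": [,]}', "json")

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_json_round_trip_on_random_compiled_rulesets(self, seed):
        rng = np.random.default_rng(seed)
        attrs = ("a", "b", "c")

        def random_tree(depth, bounds):
            if depth == 0 or rng.random() < 0.3:
                return Leaf(str(rng.choice(["severe", "less severe"])), {})
            attr = str(rng.choice(attrs))
            low, high = bounds.get(attr, (-10.0, 10.0))
            t = round(float(rng.uniform(low, high)), 3)
            if not low < t < high:
                return Leaf(str(rng.choice(["severe", "less severe"])), {})
            left = random_tree(depth - 1, {**bounds, attr: (low, t)})
            right = random_tree(depth - 1, {**bounds, attr: (t, high)})
            return Internal(attr, t, left, right, {})

        tree = DecisionTree(random_tree(3, {}), "y", ("severe", "less severe"), attrs)
        ruleset = compile_rules(tree)
        text = serialize_rules(ruleset, "json")
        assert serialize_rules(parse_rules(text, "json"), "json") == text


class TestPartitionCheck:
    def test_detects_a_coverage_gap(self):
        rules = [
            Rule("r1", (Condition("x", "lt", 0.0),), "a"),
            Rule("r2", (Condition("x", "ge", 10.0),), "b"),
        ]
        exhaustive, exclusive = check_partition(RuleSet(rules))
        assert not exhaustive and exclusive

    def test_detects_an_overlap(self):
        rules = [
            Rule("r1", (Condition("x", "lt", 10.0),), "a"),
            Rule("r2", (Condition("x", "lt", 5.0),), "b"),
        ]
        exhaustive, exclusive = check_partition(RuleSet(rules))
        assert not exclusive
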