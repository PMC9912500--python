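"""Graph construction, path rules, d-separation, and the effect classifier."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effectpath import (
    AdjustmentError,
    EffectType,
    GraphError,
    NodeRoles,
    build_dag,
    classify_adjusted_effect,
    d_separated,
    enumerate_paths,
    make_model,
    path_open,
    to_dot,
)
from conftest import all_conditioning_sets, random_dag

FIG1B_EDGES = [("E", "D"), ("E", "R0"), ("R0", "R"), ("R", "D"), ("E", "S"), ("R0", "S")]


class TestBuildDag:
    def test_single_edge(self):
        dag = build_dag([("E", "D")])
        assert dag.nodes == {"E", "D"}
        assert dag.edges == {("E", "D")}

    def test_two_cycle_rejected(self):
        with pytest.raises(GraphError, match="cycle"):
            build_dag([("E", "D"), ("D", "E")])

    def test_selection_structure_node_and_edge_counts(self):
        dag = build_dag(FIG1B_EDGES)
        assert len(dag.nodes) == 5
        assert len(dag.edges) == 6

    @pytest.mark.parametrize(
        "edges, message",
        [
            ([("E", "D"), ("E", "D")], "duplicate"),
            ([("E", "E")], "self-loop"),
            ([("A", "B"), ("B", "C"), ("C", "A")], "cycle"),
        ],
    )
    def test_invalid_edge_lists_rejected(self, edges, message):
        with pytest.raises(GraphError, match=message):
            build_dag(edges)

    def test_empty_label_rejected(self):
        with pytest.raises(GraphError):
            build_dag([("", "D")])

    def test_isolated_nodes_included(self):
        dag = build_dag([("E", "D")], isolated=["Z"])
        assert "Z" in dag.nodes


class TestEnumeratePaths:
    def test_selection_dag_has_three_exposure_outcome_paths(self, fig1b_dag):
        paths = enumerate_paths(fig1b_dag, "E", "D")
        assert [str(p) for p in paths] == [
            "E -> D",
            "E -> R0 -> R -> D",
            "E -> S <- R0 -> R -> D",
        ]
        assert [p.is_causal for p in paths] == [True, True, False]

    def test_disconnected_nodes_have_no_paths(self):
        dag = build_dag([], isolated=["A", "B"])
        assert enumerate_paths(dag, "A", "B") == []

    def test_unknown_node_rejected(self, fig1b_dag):
        with pytest.raises(GraphError, match="unknown node"):
            enumerate_paths(fig1b_dag, "E", "X")

    def test_order_is_deterministic_lexicographic(self):
        dag = build_dag([("E", "A"), ("A", "D"), ("E", "B"), ("B", "D"), ("E", "D")])
        sequences = [p.node_sequence for p in enumerate_paths(dag, "E", "D")]
        assert sequences == sorted(sequences)


class TestPathOpen:
    def setup_method(self):
        self.dag = build_dag([("E", "S"), ("R0", "S"), ("R0", "D"), ("S", "T")])

    def path(self, x, y):
        (p,) = enumerate_paths(self.dag, x, y)
        return p

    def test_unconditioned_collider_closes_the_path(self):
        assert not path_open(self.path("E", "R0"), set(), self.dag)

    def test_conditioning_on_the_collider_opens_the_path(self):
        assert path_open(self.path("E", "R0"), {"S"}, self.dag)

    def test_conditioning_on_a_collider_descendant_opens_the_path(self):
        assert path_open(self.path("E", "R0"), {"T"}, self.dag)

    def test_conditioned_chain_closes_the_path(self):
        dag = build_dag([("E", "R0"), ("R0", "D")])
        (p,) = enumerate_paths(dag, "E", "D")
        assert path_open(p, set(), dag)
        assert not path_open(p, {"R0"}, dag)

    def test_conditioned_fork_closes_the_path(self):
        dag = build_dag([("C", "E"), ("C", "D")])
        (p,) = enumerate_paths(dag, "E", "D")
        assert not path_open(p, {"C"}, dag)


class TestDSeparation:
    def test_direct_edge_is_never_separated(self, fig1b_dag):
        assert not d_separated(fig1b_dag, "E", "R0", set())

    def test_selection_conditioning_induces_association(self):
        dag = build_dag([("E", "S"), ("R0", "S")])
        assert d_separated(dag, "E", "R0", set())
        assert not d_separated(dag, "E", "R0", {"S"})

    def test_unknown_node_rejected(self, fig1b_dag):
        with pytest.raises(GraphError):
            d_separated(fig1b_dag, "E", "X", set())

    def test_endpoint_in_conditioning_set_rejected(self, fig1b_dag):
        with pytest.raises(GraphError):
            d_separated(fig1b_dag, "E", "D", {"E"})

    def test_agrees_with_exhaustive_path_rules_on_random_dags(self):
        rng = random.Random(20230210)
        for _ in range(40):
            dag = random_dag(rng)
            for x, y in itertools.combinations(sorted(dag.nodes), 2):
                paths = enumerate_paths(dag, x, y)
                for cond in all_conditioning_sets(dag, x, y):
                    oracle = not any(path_open(p, cond, dag) for p in paths)
                    assert d_separated(dag, x, y, cond) == oracle

    def test_collider_descendant_conditioning_only_opens(self):
        """Adding a collider descendant to the conditioning set can only
        switch the collider's step from blocking to open, never back."""
        rng = random.Random(7)
        for _ in range(25):
            dag = random_dag(rng, max_nodes=6)
            for x, y in itertools.combinations(sorted(dag.nodes), 2):
                for p in enumerate_paths(dag, x, y):
                    for i in range(1, len(p.node_sequence) - 1):
                        if not p.is_collider_at(i):
                            continue
                        node = p.node_sequence[i]
                        others = frozenset(p.node_sequence) - {node}
                        for desc in dag.descendants(node) - others:
                            base = path_open(p, set(), dag)
                            opened = path_open(p, {desc}, dag)
                            assert opened or not base


MODEL_VERDICTS = [
    # (template, adjustment set, expected effect type)
    ("fig1b", {"R"}, EffectType.CONTROLLED_DIRECT),
    ("fig1b", set(), EffectType.BIASED),
    ("fig1c", {"R"}, EffectType.BIASED),
    ("fig1c", {"R", "C"}, EffectType.CONTROLLED_DIRECT),
    ("fig1c", set(), EffectType.BIASED),
    ("fig1d_timeconstant", {"R"}, EffectType.TOTAL),
    ("fig1d_timeconstant", set(), EffectType.BIASED),
    ("modelC", {"R"}, EffectType.CONTROLLED_DIRECT),
    ("modelC", set(), EffectType.TOTAL),
    ("modelD", set(), EffectType.TOTAL),
    ("modelD", {"R"}, EffectType.TOTAL),
    ("fig1d_postmigration", {"R", "C"}, EffectType.CONTROLLED_DIRECT),
    ("fig1d_postmigration", set(), EffectType.BIASED),
]


class TestClassifier:
    @pytest.mark.parametrize("template, adjust, expected", MODEL_VERDICTS)
    def test_template_verdicts(self, template, adjust, expected):
        model = make_model(template)
        result = classify_adjusted_effect(model.dag, model.roles, adjust)
        assert result.effect_type is expected

    def test_biased_iff_open_noncausal_paths(self, fig1b_model):
        biased = classify_adjusted_effect(fig1b_model.dag, fig1b_model.roles, set())
        assert biased.effect_type is EffectType.BIASED
        assert [str(p) for p in biased.open_noncausal_paths] == [
            "E -> S <- R0 -> R -> D"
        ]
        cde = classify_adjusted_effect(fig1b_model.dag, fig1b_model.roles, {"R"})
        assert not cde.open_noncausal_paths
        assert [str(p) for p in cde.blocked_causal_paths] == ["E -> R0 -> R -> D"]

    def test_selection_blocked_causal_path_counts_as_controlled_direct(self):
        """A directed E -> S -> R -> D path blocked by the S = 1 restriction
        (and the mediator adjustment) turns the estimand into a controlled
        direct effect even with no biasing path left open."""
        model = make_model("fig1d_postmigration")
        result = classify_adjusted_effect(model.dag, model.roles, {"R", "C"})
        assert result.effect_type is EffectType.CONTROLLED_DIRECT
        assert any(
            "S" in p.node_sequence for p in result.blocked_causal_paths
        )

    def test_adjusting_exposure_outcome_or_unmeasured_rejected(self, fig1b_model):
        dag, roles = fig1b_model.dag, fig1b_model.roles
        with pytest.raises(AdjustmentError):
            classify_adjusted_effect(dag, roles, {"D"})
        with pytest.raises(AdjustmentError):
            classify_adjusted_effect(dag, roles, {"E"})
        with pytest.raises(AdjustmentError, match="unmeasured"):
            classify_adjusted_effect(dag, roles, {"R0"})
        with pytest.raises(AdjustmentError):
            classify_adjusted_effect(dag, roles, {"S"})

    @given(st.permutations(["E", "D", "R0", "R", "S"]))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_verdict_invariant_under_relabeling(self, permuted):
        """Relabeling nodes (role-preserving isomorphism) cannot change the
        verdict of any adjustment strategy."""
        mapping = dict(zip(["E", "D", "R0", "R", "S"], permuted))
        dag = build_dag([(mapping[a], mapping[b]) for a, b in FIG1B_EDGES])
        roles = NodeRoles(
            exposure=mapping["E"],
            outcome=mapping["D"],
            selection=mapping["S"],
            risk_factors_pre={mapping["R0"]},
            risk_factors_measured={mapping["R"]},
            measured={mapping["R"]},
        )
        for adjust, expected in [
            (set(), EffectType.BIASED),
            ({mapping["R"]}, EffectType.CONTROLLED_DIRECT),
        ]:
            assert (
                classify_adjusted_effect(dag, roles, adjust).effect_type is expected
            )


class TestRolesAndExport:
    def test_exposure_equal_outcome_rejected(self):
        with pytest.raises(GraphError):
            NodeRoles(exposure="E", outcome="E")

    def test_unmeasured_risk_factor_cannot_be_declared_measured(self):
        with pytest.raises(GraphError):
            NodeRoles(
                exposure="E", outcome="D",
                risk_factors_pre={"R0"}, measured={"R0"},
            )

    def test_dot_export_marks_selection_and_unmeasured(self, fig1b_model):
        dot = to_dot(fig1b_model.dag, fig1b_model.roles)
        assert dot.startswith("digraph")
        assert '"E" -> "D";' in dot
        assert "peripheries=2" in dot  # circled selection node
        assert "gray" in dot  # unmeasured pre-migration factor
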