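"""Structural models: templates, simulation, interventions, ground truth."""

import numpy as np
import pytest
import statsmodels.api as sm

from effectpath import (
    AnalyticError,
    ModelError,
    analytic_effects,
    apply_do,
    make_model,
    mc_effects,
    simulate_cohort,
)
from effectpath.scm import LinearNode, LogisticNode, derive_seed


class TestMakeModel:
    def test_selection_template_structure(self):
        model = make_model("fig1b")
        assert model.dag.nodes == {"E", "R0", "R", "S", "D"}
        assert len(model.dag.edges) == 6
        assert model.roles.selection == "S"

    def test_postmigration_variant_adds_selection_to_mediator_arrow(self):
        base = make_model("fig1d")
        variant = make_model("fig1d_postmigration")
        assert variant.dag.edges == base.dag.edges | {("S", "R")}
        assert variant.assignments["R"].coefficients["S"] == 0.5

    def test_coefficient_override_on_absent_edge_rejected(self):
        with pytest.raises(ModelError, match="absent edge"):
            make_model("fig1b", coefficients={("E", "C"): 0.2})

    def test_coefficient_override_applied(self):
        model = make_model("fig1b", coefficients={"E->D": 0.0})
        assert model.assignments["D"].coefficients["E"] == 0.0
        assert analytic_effects(model).cde == 0.0

    def test_unknown_template_rejected(self):
        with pytest.raises(ModelError, match="unknown template"):
            make_model("fig9z")

    def test_interaction_attached_to_outcome(self):
        model = make_model("fig1b", interaction=0.2)
        assert model.assignments["D"].interaction == ("E", "R", 0.2)

    def test_time_constant_variant_merges_risk_factor(self):
        model = make_model("fig1d_timeconstant")
        assert "R0" not in model.dag.nodes
        assert ("R", "S") in model.dag.edges
        assert "R" in model.roles.measured


class TestSimulateCohort:
    def test_same_seed_gives_bit_identical_tables(self):
        model = make_model("fig1b")
        a = simulate_cohort(model, 2_000, 11)
        b = simulate_cohort(model, 2_000, 11)
        assert a.full_population.equals(b.full_population)
        assert not a.full_population.equals(
            simulate_cohort(model, 2_000, 12).full_population
        )

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ModelError):
            simulate_cohort(make_model("fig1b"), 0, 1)

    def test_selected_view_is_the_s1_subsample(self):
        cohort = simulate_cohort(make_model("fig1b"), 20_000, 5)
        sel = cohort.selected
        assert (sel["S"] == 1.0).all()
        assert 0 < len(sel) < cohort.n
        assert set(cohort.full_population.columns) == {"E", "R0", "R", "S", "D"}

    def test_parameter_recovery_within_three_standard_errors(self):
        """Regressing each node on its parents recovers every generating
        coefficient, so the simulator draws from the declared assignments."""
        model = make_model("fig1b")
        df = simulate_cohort(model, 100_000, 20230210).full_population
        for node, a in model.assignments.items():
            if isinstance(a, LinearNode) and a.coefficients:
                X = sm.add_constant(df[sorted(a.coefficients)], prepend=True)
                res = sm.OLS(df[node], X).fit()
                for parent, true in a.coefficients.items():
                    assert abs(res.params[parent] - true) < 3 * res.bse[parent]
            elif isinstance(a, LogisticNode):
                X = sm.add_constant(df[sorted(a.coefficients)], prepend=True)
                res = sm.Logit(df[node], X).fit(disp=0)
                assert abs(res.params["const"] - a.intercept) < 3 * res.bse["const"]
                for parent, true in a.coefficients.items():
                    assert abs(res.params[parent] - true) < 3 * res.bse[parent]

    def test_collider_bias_appears_only_in_selected_view(self):
        """With no exposure effect on the risk factor, exposure and the
        pre-migration factor are independent in the full population but
        strongly associated once restricted to the selected dataset."""
        cohort = simulate_cohort(make_model("fig1d"), 100_000, 20230210)
        full = cohort.full_population
        sel = cohort.selected
        r_full = np.corrcoef(full["E"], full["R0"])[0, 1]
        r_sel = np.corrcoef(sel["E"], sel["R0"])[0, 1]
        assert abs(r_full) < 3 / np.sqrt(len(full))
        assert abs(r_sel) > 5 / np.sqrt(len(sel))

    def test_implied_independencies_hold_in_data(self):
        """Partial correlations for d-separated pairs are statistically zero."""
        model = make_model("fig1b")
        df = simulate_cohort(model, 100_000, 31).full_population
        # E.g. D _||_ R0 | {E, R} and R _||_ E | R0 in the full population.
        for y, x, given in [("D", "R0", ["E", "R"]), ("R", "E", ["R0"])]:
            X = sm.add_constant(df[[x] + given], prepend=True)
            res = sm.OLS(df[y], X).fit()
            assert abs(res.params[x]) < 3 * res.bse[x]


class TestApplyDo:
    def test_do_fixes_node_and_severs_incoming_edges(self):
        model = make_model("fig1b")
        intervened = apply_do(model, {"R": 1.5})
        assert ("R0", "R") not in intervened.dag.edges
        assert ("R", "D") in intervened.dag.edges
        df = simulate_cohort(intervened, 100, 3).full_population
        assert (df["R"] == 1.5).all()

    def test_do_on_unknown_node_rejected(self):
        with pytest.raises(ModelError):
            apply_do(make_model("fig1b"), {"X": 1.0})

    def test_selected_view_after_do_on_selection_is_contradictory(self):
        model = make_model("fig1b")
        cohort = simulate_cohort(apply_do(model, {"S": 0.0}), 100, 3)
        with pytest.raises(ModelError, match="do-intervention"):
            cohort.selected

    def test_do_leaves_nondescendants_unchanged(self):
        """Intervening on the exposure must not perturb the distribution of
        nodes it does not cause (here the confounder C)."""
        model = make_model("fig1c")
        natural = simulate_cohort(model, 100_000, 17).full_population
        dosed = simulate_cohort(apply_do(model, {"E": 1.0}), 100_000, 17).full_population
        assert np.array_equal(natural["C"], dosed["C"])


class TestGroundTruth:
    def test_path_tracing_total_and_direct(self):
        truths = analytic_effects(make_model("fig1b"))
        # direct 0.3 plus mediated 0.5 * 1.0 * 0.4
        assert truths.total_effect == pytest.approx(0.5)
        assert truths.cde == pytest.approx(0.3)

    def test_no_mediation_limit_total_equals_direct(self):
        model = make_model("fig1b", coefficients={"E->R0": 0.0})
        truths = analytic_effects(model)
        assert truths.total_effect == pytest.approx(0.3)
        assert truths.cde == pytest.approx(0.3)

    def test_interaction_shifts_cde_with_mediator_level(self):
        model = make_model("fig1b", interaction=0.2)
        assert analytic_effects(model, m_reference=1.0).cde == pytest.approx(0.5)
        assert analytic_effects(model, m_reference=0.0).cde == pytest.approx(0.3)

    def test_analytic_refused_when_selection_mediates(self):
        with pytest.raises(AnalyticError, match="mc_effects"):
            analytic_effects(make_model("fig1d_postmigration"))

    @pytest.mark.parametrize("template", ["fig1a", "fig1b", "fig1c", "modelC", "modelD", "fig1d"])
    def test_monte_carlo_agrees_with_path_tracing(self, template):
        model = make_model(template)
        truths = analytic_effects(model)
        mc = mc_effects(model, 50_000, 2024)
        se = max(mc.mc_se or 0.0, 1e-12)
        assert abs(mc.total_effect - truths.total_effect) <= 3 * se
        assert mc.cde == pytest.approx(truths.cde, abs=1e-9)

    def test_monte_carlo_reports_both_total_targets_when_selection_mediates(self):
        mc = mc_effects(make_model("fig1d_postmigration"), 400_000, 2024)
        assert mc.total_effect_excluding_S_paths == pytest.approx(0.3, abs=1e-6)
        # the selection-mediated pathway shrinks the headline total
        assert mc.total_effect < 0.3 - 3 * mc.mc_se
        assert mc.method == "monte_carlo"

    def test_noiseless_model_contrast_is_exactly_the_direct_coefficient(self):
        model = make_model(
            "fig1b",
            coefficients={"E->R0": 0.0},
            noise_sds={"R0": 0.0, "R": 0.0, "D": 0.0},
        )
        mc = mc_effects(model, 500, 1)
        assert mc.total_effect == pytest.approx(0.3, abs=1e-12)


def test_derived_seeds_are_stable_distinct_and_below_2_31():
    seeds = {derive_seed(1, "a", i) for i in range(100)}
    assert len(seeds) == 100
    assert all(0 <= s < 2**31 for s in seeds)
    assert derive_seed(1, "a", 0) == derive_seed(1, "a", 0)
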