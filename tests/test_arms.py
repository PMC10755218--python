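"""Arm derivation, intervention costing, and tree construction."""

import math

import pytest

from psilocea import (
    build_arm_tree,
    derive_arm_probabilities,
    enumerate_paths,
    evaluate,
    intervention_cost,
    relapse_incremental_cost,
)
from psilocea.arms import ARM_IDS, DerivationError
from psilocea.parameters import ArmProbabilities, RelativeRisks


def _arm(p_complete=0.8, rem=0.3, resp=0.4, relapse=0.2):
    return ArmProbabilities(
        p_complete=p_complete,
        completer={
            "p_remission": rem,
            "p_response": resp,
            "p_no_response": 1 - rem - resp,
        },
        dropout={
            "p_spont_remission": 0.1,
            "p_improve_no_remission": 0.2,
            "p_no_improvement": 0.7,
        },
        p_relapse=relapse,
    )


class TestDeriveArmProbabilities:
    def test_identity_relative_risks(self):
        ssri = _arm()
        rr = RelativeRisks(rr_dropout=1, rr_response=1, rr_remission=1)
        derived = derive_arm_probabilities(ssri, rr)
        assert derived == ssri

    def test_cbt_relative_risks_with_residual(self):
        ssri = _arm(rem=0.3, resp=0.4)
        rr = RelativeRisks(rr_dropout=0.62, rr_response=0.97, rr_remission=1.11)
        derived = derive_arm_probabilities(ssri, rr)
        assert derived.completer.p_remission == pytest.approx(0.333)
        assert derived.completer.p_response == pytest.approx(0.388)
        assert derived.completer.p_no_response == pytest.approx(0.279)
        assert derived.p_dropout == pytest.approx(0.62 * 0.2)

    def test_scaled_probability_above_one_is_an_error(self):
        ssri = _arm(rem=0.9, resp=0.05)
        rr = RelativeRisks(rr_dropout=1, rr_response=1, rr_remission=1.27)
        with pytest.raises(DerivationError, match="rr_remission"):
            derive_arm_probabilities(ssri, rr)

    def test_negative_residual_is_an_error(self):
        ssri = _arm(rem=0.5, resp=0.45)
        rr = RelativeRisks(rr_dropout=1, rr_response=1.2, rr_remission=1.3)
        with pytest.raises(DerivationError, match="residual"):
            derive_arm_probabilities(ssri, rr)


class TestInterventionCost:
    def test_pap_itemisation_at_full_drug_weight(self, params):
        params.costs.drug_cost_weight = 1.0
        cost = intervention_cost("pap", params, price=400)
        assert cost.drug == 400
        assert cost.therapist == pytest.approx(38 * 87)
        assert cost.completer_total == pytest.approx(3706)
        # itemised components sum to the totals
        assert cost.completer_total == cost.drug + cost.therapist + cost.medication + cost.cbt_course

    def test_pap_zero_price_leaves_therapist_cost_only(self, params):
        cost = intervention_cost("pap", params, price=0)
        assert cost.drug == 0
        assert cost.completer_total == pytest.approx(38 * 87)

    def test_expected_pap_cost_slope_equals_drug_weight(self, base_params):
        lo = evaluate(build_arm_tree("pap", base_params, 400))
        hi = evaluate(build_arm_tree("pap", base_params, 2000))
        slope = (hi.expected_cost_healthcare - lo.expected_cost_healthcare) / 1600
        assert slope == pytest.approx(base_params.costs.drug_cost_weight)

    def test_ssri_medication_for_completers_only(self, base_params):
        cost = intervention_cost("ssri", base_params)
        assert cost.dropout_total == 0
        assert cost.medication == pytest.approx(
            base_params.costs.ssri_daily_cost * base_params.costs.ssri_days
        )

    def test_dropout_fraction_applies_to_cbt_course(self, base_params):
        cost = intervention_cost("cbt", base_params)
        assert cost.dropout_cbt_course == pytest.approx(0.5 * 1050)

    def test_negative_price_rejected(self, base_params):
        with pytest.raises(ValueError):
            intervention_cost("pap", base_params, price=-5)


class TestRelapseIncrementalCost:
    def test_halving_rule(self):
        assert relapse_incremental_cost(2000, 600) == pytest.approx(700)

    def test_zero(self):
        assert relapse_incremental_cost(0, 0) == 0

    @pytest.mark.parametrize("x", [1.0, 137.5, 5651.75])
    def test_equal_costs_cancel(self, x):
        assert relapse_incremental_cost(x, x) == 0

    def test_maintenance_above_relapse_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            assert relapse_incremental_cost(100, 300) == pytest.approx(-100)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            relapse_incremental_cost(-1, 0)


class TestBuildArmTree:
    @pytest.mark.parametrize("arm_id", ARM_IDS)
    def test_ten_leaves_and_conservation(self, base_params, arm_id):
        paths = enumerate_paths(build_arm_tree(arm_id, base_params, 400))
        assert len(paths) == 10
        assert math.fsum(p.probability for p in paths) == pytest.approx(1, abs=1e-12)

    def test_zero_relapse_matches_no_relapse_model(self, params):
        params.pap.p_relapse = 0.0
        tree = build_arm_tree("pap", params, 400)
        for path in enumerate_paths(tree):
            if "relapse/" not in path.leaf_id and path.leaf_id.endswith("/relapse"):
                assert path.probability == 0.0
        res = evaluate(tree)
        # no leaf with relapse mass: expectation equals the 6-state model
        manual = sum(
            p.probability * p.qaly
            for p in enumerate_paths(tree)
            if not p.leaf_id.endswith("/relapse")
        )
        assert res.expected_qalys == pytest.approx(manual, abs=1e-12)

    def test_full_completion_empties_dropout_subtree(self, params):
        params.pap.p_complete = 1.0
        for path in enumerate_paths(build_arm_tree("pap", params, 400)):
            if path.leaf_id.startswith("dropout"):
                assert path.probability == 0.0

    @pytest.mark.parametrize("u", [0.0, 0.3, 1.0])
    def test_equal_utilities_collapse_qalys_to_half_year(self, params, u):
        """With every state utility equal to u, each arm accrues u * 26/52."""
        for fld in ("u_remission", "u_response", "u_no_response", "u_relapse"):
            setattr(params.utilities, fld, u)
        params.utilities.u_baseline = None
        for arm_id in ARM_IDS:
            res = evaluate(build_arm_tree(arm_id, params, 400))
            assert res.expected_qalys == pytest.approx(u * 0.5, abs=1e-12)

    def test_cost_monotone_in_price_and_outcome_costs(self, params):
        base = evaluate(build_arm_tree("pap", params, 400)).expected_cost_healthcare
        assert evaluate(build_arm_tree("pap", params, 900)).expected_cost_healthcare >= base
        params.costs.c_no_response += 500
        assert (
            evaluate(build_arm_tree("pap", params, 400)).expected_cost_healthcare
            >= base
        )

    def test_cbt_cost_monotone_in_course_cost(self, params):
        base = evaluate(build_arm_tree("cbt", params, 400)).expected_cost_healthcare
        params.costs.cbt_course_cost *= 1.5
        assert evaluate(build_arm_tree("cbt", params, 400)).expected_cost_healthcare > base

    def test_qalys_monotone_in_relapse_and_remission_utility(self, params):
        base = evaluate(build_arm_tree("pap", params, 400)).expected_qalys
        params.pap.p_relapse = min(1.0, params.pap.p_relapse + 0.2)
        worse = evaluate(build_arm_tree("pap", params, 400)).expected_qalys
        assert worse <= base
        params.utilities.u_remission = min(1.0, params.utilities.u_remission + 0.05)
        assert evaluate(build_arm_tree("pap", params, 400)).expected_qalys >= worse

    def test_tree_json_serialisation(self, base_params):
        d = build_arm_tree("combo", base_params, 600).to_json_dict()
        assert d["arm_id"] == "combo"
        assert {b["node"]["id"] for b in d["root"]["branches"]} == {"complete", "dropout"}
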