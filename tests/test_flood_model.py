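"""Flood network calibration, utilities, CQALY and cost-effectiveness."""

import pytest

from floodbn import (
    FloodNetworkConfig,
    InterventionScenario,
    UtilityTable,
    beta_mean,
    build_flood_network,
    change_in_utility,
    compute_cqaly,
    default_scenario,
    default_utilities,
    evaluate_intervention,
    enumerate_joint,
    marginal,
    validate_network,
)
from floodbn.flood_model import FLOOD_MARGINALS, round_half_away


ELICITED = {
    "Flood": 0.201,
    "LOSI": 0.62,
    "PPD": 0.186,
    "Lsever": 0.483,
    "Msever": 0.211,
}


class TestBuildFloodNetwork:
    def test_network_is_valid(self, flood_net):
        assert validate_network(flood_net) == []

    @pytest.mark.parametrize("node, prevalence", sorted(ELICITED.items()))
    def test_marginals_honor_elicited_prevalences(self, flood_net, node, prevalence):
        assert marginal(flood_net, node)["present"] == pytest.approx(
            prevalence, abs=1e-9
        )

    def test_all_marginals_hold_simultaneously(self, flood_net):
        """Calibration of one child must not disturb another's marginal."""
        joint = enumerate_joint(flood_net)
        for node, prevalence in ELICITED.items():
            axis_keep = joint.scope.index(node)
            axes = tuple(i for i in range(len(joint.scope)) if i != axis_keep)
            m = joint.values.sum(axis=axes)[0]  # index 0 = "present"
            assert m == pytest.approx(prevalence, abs=1e-9)

    def test_feasible_risk_ratio_is_respected(self):
        """Where ratio 2 is feasible, exposed risk is exactly twice baseline."""
        net = build_flood_network()
        cpt = net.cpt("Lsever")  # marginal 0.483, parent PPD: ratio 2 feasible
        p_exposed = cpt.row(("present",))[0]
        p_baseline = cpt.row(("absent",))[0]
        assert p_exposed == pytest.approx(2.0 * p_baseline, rel=1e-9)

    def test_infeasible_ratio_clamped_with_warning(self, caplog):
        # LOSI's 62% marginal cannot support an exposed/unexposed ratio of 2
        with caplog.at_level("WARNING", logger="floodbn.flood_model"):
            net = build_flood_network()
        assert any("infeasible" in r.message for r in caplog.records)
        assert net.cpt("LOSI").row(("present",))[0] == pytest.approx(1.0)
        assert marginal(net, "LOSI")["present"] == pytest.approx(0.62, abs=1e-9)

    def test_custom_risk_ratio(self):
        net = build_flood_network(FloodNetworkConfig(risk_ratio=1.5))
        for node, prevalence in ELICITED.items():
            assert marginal(net, node)["present"] == pytest.approx(
                prevalence, abs=1e-9
            )
        cpt = net.cpt("Msever")
        assert cpt.row(("present",))[0] == pytest.approx(
            1.5 * cpt.row(("absent",))[0], rel=1e-9
        )

    def test_bad_marginal_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            FloodNetworkConfig(marginals={**FLOOD_MARGINALS, "Flood": 1.2})

    def test_missing_node_rejected(self):
        with pytest.raises(ValueError, match="missing marginals"):
            FloodNetworkConfig(marginals={"Flood": 0.2})


class TestUtilities:
    def test_change_in_utility_printed_values(self):
        u = default_utilities()
        assert round(change_in_utility(u, "Lsever"), 2) == 0.25
        assert round(change_in_utility(u, "Msever"), 2) == 0.43
        assert change_in_utility(u, "Remission") == 0.0

    @pytest.mark.parametrize(
        "alpha, beta, printed",
        [(923, 163, 0.85), (182, 122, 0.60), (54, 75, 0.42)],
    )
    def test_beta_means_match_elicited_utilities(self, alpha, beta, printed):
        assert round(beta_mean(alpha, beta), 2) == printed
        assert abs(beta_mean(alpha, beta) - printed) < 0.005

    def test_uniform_beta_mean(self):
        assert beta_mean(1, 1) == 0.5

    def test_nonpositive_beta_parameters_rejected(self):
        with pytest.raises(ValueError):
            beta_mean(0, 2)
        with pytest.raises(ValueError):
            beta_mean(2, -1)

    def test_inconsistent_mean_rejected(self):
        with pytest.raises(ValueError, match="disagrees"):
            UtilityTable(
                {"Remission": (0.85, 923, 163), "Lsever": (0.70, 182, 122)}
            )

    def test_unknown_state_rejected(self):
        with pytest.raises(KeyError, match="Severe"):
            change_in_utility(default_utilities(), "Severe")


class TestComputeCqaly:
    def test_zero_cu_gives_zero(self, flood_net):
        u = UtilityTable(
            {"Remission": (0.85, 923, 163), "Msever": (0.85, 923, 163)}
        )
        assert compute_cqaly(flood_net, u, "Msever") == 0.0

    def test_hand_computed_toy_pathway(self):
        """P(state ∧ LOSI | Flood) = 0.5 with CU 0.43 gives 0.215."""
        from conftest import (
            BayesianNetwork,
            ConditionalProbabilityTable,
            DagStructure,
            binary,
            root_cpt,
        )

        # Flood -> LOSI (deterministic), LOSI -> Msever (fair coin):
        # given Flood=present, P(LOSI=present)=1 and P(Msever=present)=0.5
        structure = DagStructure(
            (binary("Flood"), binary("LOSI"), binary("Msever")),
            (("Flood", "LOSI"), ("LOSI", "Msever")),
        )
        net = BayesianNetwork(
            structure,
            {
                "Flood": root_cpt("Flood", 0.3),
                "LOSI": ConditionalProbabilityTable(
                    "LOSI",
                    ("Flood",),
                    {("present",): (1.0, 0.0), ("absent",): (0.2, 0.8)},
                ),
                "Msever": ConditionalProbabilityTable(
                    "Msever",
                    ("LOSI",),
                    {("present",): (0.5, 0.5), ("absent",): (0.1, 0.9)},
                ),
            },
        )
        u = default_utilities()
        assert compute_cqaly(net, u, "Msever") == pytest.approx(
            0.5 * change_in_utility(u, "Msever"), abs=1e-12
        )
        assert compute_cqaly(net, u, "Msever") == pytest.approx(0.215, abs=0.005)

    def test_matches_enumeration_oracle(self, flood_net):
        u = default_utilities()
        joint = enumerate_joint(flood_net)
        names = joint.scope
        idx = {v: i for i, v in enumerate(names)}

        def mass(fixed):
            total = 0.0
            import itertools as it

            for cell in it.product(range(2), repeat=len(names)):
                if all(cell[idx[v]] == (0 if s == "present" else 1) for v, s in fixed.items()):
                    total += joint.values[cell]
            return total

        for state in ("Lsever", "Msever"):
            p_path = (
                mass({state: "present", "LOSI": "present", "Flood": "present"})
                / mass({"Flood": "present"})
            )
            expected = p_path * change_in_utility(u, state) * u.horizon
            assert compute_cqaly(flood_net, u, state) == pytest.approx(
                expected, abs=1e-9
            )

    def test_override_wins(self, flood_net):
        u = default_utilities()
        assert compute_cqaly(flood_net, u, "Msever", override=0.055) == 0.055

    def test_reference_state_rejected(self, flood_net):
        with pytest.raises(ValueError, match="reference"):
            compute_cqaly(flood_net, default_utilities(), "Remission")


class TestEvaluateIntervention:
    def test_printed_before_after_reproduces_published_money(self):
        result = evaluate_intervention(default_scenario())
        assert result.delta_qaly("Msever") == pytest.approx(0.022, abs=1e-12)
        assert result.delta_qaly("Lsever") == pytest.approx(0.024, abs=1e-12)
        assert result.monetary_value_rounded("Msever") == 440.0
        assert result.monetary_value_rounded("Lsever") == 480.0

    def test_null_intervention_is_free(self):
        scn = InterventionScenario(
            "null", {"Msever": 0.05, "Lsever": 0.06}, {"Msever": 0.05, "Lsever": 0.06}
        )
        result = evaluate_intervention(scn)
        for state in ("Msever", "Lsever"):
            assert result.delta_qaly(state) == 0.0
            assert result.monetary_value(state) == 0.0

    @pytest.mark.parametrize(
        "threshold, msever, lsever",
        [(20_000, 440, 480), (30_000, 660, 720), (25_000, 550, 600)],
    )
    def test_monetary_value_linear_in_threshold(self, threshold, msever, lsever):
        scn = default_scenario()
        scn = InterventionScenario(scn.label, scn.before, scn.after, threshold)
        result = evaluate_intervention(scn)
        assert result.monetary_value_rounded("Msever") == msever
        assert result.monetary_value_rounded("Lsever") == lsever

    def test_network_form_scenario(self):
        """Before/after supplied as network configs: the intervention lowers
        the loss-of-sentimental-items prevalence."""
        before = FloodNetworkConfig()
        after = FloodNetworkConfig(
            marginals={**FLOOD_MARGINALS, "LOSI": 0.40, "PPD": 0.12,
                       "Lsever": 0.30, "Msever": 0.13}
        )
        result = evaluate_intervention(
            InterventionScenario("early warning", before, after)
        )
        for state in ("Msever", "Lsever"):
            assert result.delta_qaly(state) > 0
            assert result.monetary_value(state) == pytest.approx(
                result.delta_qaly(state) * 20_000
            )

    def test_mixed_forms_rejected(self):
        with pytest.raises(ValueError, match="same form"):
            InterventionScenario(
                "bad", FloodNetworkConfig(), {"Msever": 0.03, "Lsever": 0.04}
            )

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            InterventionScenario(
                "bad", {"Msever": 0.05}, {"Msever": 0.03}, threshold=0
            )

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(440.5) == 441.0
        assert round_half_away(-440.5) == -441.0
        assert round_half_away(440.4) == 440.0
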