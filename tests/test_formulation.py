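"""Threshold-degree selection: AC_PT, PT_P, best binders and the IF union."""

import pytest

from phytoformula import (
    ConfigError,
    FormulationConfig,
    LayeredNetwork,
    UsageError,
    ideal_formulation,
    select_ac_pt,
    select_ac_ptp,
    select_pt_p,
)
from phytoformula.synthetic import GeneratorConfig, generate

PAPER_PT_P = frozenset({"PT14", "PT47", "PT52", "PT56"})


class TestSelectAcPt:
    def test_threshold_four_selects_the_five_hub_compounds(self, network):
        selected = select_ac_pt(network, FormulationConfig())
        assert selected == {"AC2", "AC3", "AC5", "AC6", "AC11"}

    def test_threshold_one_selects_every_connected_compound(self, network):
        config = FormulationConfig(compound_threshold=1)
        report = network.compound_target_degree()
        expected = {c for c, d in report.degrees.items() if d >= 1}
        assert select_ac_pt(network, config) == expected

    def test_threshold_above_max_degree_is_empty_not_error(self, network):
        assert select_ac_pt(network, FormulationConfig(compound_threshold=9)) == set()

    def test_matches_brute_force_filter_on_synthetic_networks(self):
        for seed in range(10):
            reg, _ = generate(GeneratorConfig(seed=seed))
            net = LayeredNetwork(reg)
            counts = {}
            for e in reg.edges:
                if e.kind in ("targets_direct", "targets_indirect"):
                    counts[e.source] = counts.get(e.source, 0) + 1
            expected = {c for c, d in counts.items() if d >= 4}
            assert select_ac_pt(net, FormulationConfig()) == expected


class TestSelectPtP:
    def test_override_set_returned_verbatim(self, network):
        config = FormulationConfig(pt_p_override=PAPER_PT_P)
        assert select_pt_p(network, config) == set(PAPER_PT_P)

    def test_override_with_unknown_code_raises(self, network):
        config = FormulationConfig(pt_p_override=frozenset({"PT14", "PT99"}))
        with pytest.raises(UsageError):
            select_pt_p(network, config)

    def test_derived_from_pathway_layer_matches_curated_set(self, network):
        assert select_pt_p(network, FormulationConfig()) == set(PAPER_PT_P)

    def test_threshold_one_selects_every_target_with_a_pathway(self, network):
        config = FormulationConfig(pathway_threshold=1)
        report = network.degree("PT-P", "left")
        assert select_pt_p(network, config) == {
            t for t, d in report.degrees.items() if d >= 1
        }

    def test_planted_multipathway_targets_recovered(self):
        reg, truth = generate(GeneratorConfig(seed=5))
        net = LayeredNetwork(reg)
        assert select_pt_p(net, FormulationConfig()) == truth.multipathway_targets


class TestSelectAcPtp:
    def test_sole_binders_win_their_targets(self, network):
        chosen, trace, unbound = select_ac_ptp(network, set(PAPER_PT_P), FormulationConfig())
        assert chosen == {"PT14": "AC6", "PT47": "AC58", "PT52": "AC6", "PT56": "AC54"}
        assert unbound == set()

    def test_empty_target_set_gives_empty_map(self, network):
        chosen, trace, unbound = select_ac_ptp(network, set(), FormulationConfig())
        assert chosen == {} and trace == {} and unbound == set()

    def test_unbound_target_reported_not_fatal(self, network):
        # PT54 has no compound edges in the curated subset
        chosen, _, unbound = select_ac_ptp(network, {"PT54"}, FormulationConfig())
        assert chosen == {} and unbound == {"PT54"}

    def test_trace_ranks_by_degree_then_code(self, network):
        _, trace, _ = select_ac_ptp(network, {"PT14"}, FormulationConfig())
        ranked = trace["PT14"]
        degrees = [d for _, d in ranked]
        assert degrees == sorted(degrees, reverse=True)


class TestIdealFormulation:
    def test_reproduces_published_seven_compound_set(self, network):
        config = FormulationConfig(pt_p_override=PAPER_PT_P)
        result = ideal_formulation(network, config)
        assert result.ideal_formulation == {
            "AC2", "AC3", "AC5", "AC6", "AC11", "AC54", "AC58",
        }
        assert result.ideal_formulation == result.ac_pt | set(result.ac_ptp.values())

    def test_loose_thresholds_give_superset(self, network):
        tight = ideal_formulation(network, FormulationConfig())
        loose = ideal_formulation(
            network, FormulationConfig(compound_threshold=1, pathway_threshold=1)
        )
        assert tight.ideal_formulation <= loose.ideal_formulation

    def test_anti_monotone_in_both_thresholds(self, network):
        prev = None
        for t in (1, 2, 4, 6, 9):
            result = ideal_formulation(
                network, FormulationConfig(compound_threshold=t, pathway_threshold=t)
            )
            if prev is not None:
                assert result.ideal_formulation <= prev
            prev = result.ideal_formulation

    def test_every_member_justified_by_trace(self, network):
        result = ideal_formulation(network, FormulationConfig())
        for compound in result.ideal_formulation:
            in_ac_pt = result.compound_degrees.get(compound, 0) >= 4
            binds_ptp = compound in set(result.ac_ptp.values())
            assert in_ac_pt or binds_ptp

    def test_planted_structure_recovered_on_synthetic(self):
        for seed in range(10):
            reg, truth = generate(GeneratorConfig(seed=seed))
            result = ideal_formulation(LayeredNetwork(reg), FormulationConfig())
            assert result.ac_pt == truth.hub_compounds
            assert result.ideal_formulation == truth.expected_if

    def test_thresholds_below_one_rejected(self):
        with pytest.raises(ConfigError):
            FormulationConfig(compound_threshold=0)
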