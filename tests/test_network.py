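"""Layer degrees, hubs, coverage and shared-target partners."""

import pytest

from phytoformula import LayeredNetwork, Registry, UsageError, hubs
from phytoformula.registry import DIABETES_TARGET_KINDS, NodeRecord
from phytoformula.synthetic import GeneratorConfig, generate


def brute_degree(edges, side, kinds):
    """Independent count straight off the raw edge tuples."""
    out = {}
    for e in edges:
        node = e.source if side == "left" else e.target
        out.setdefault(node, 0)
        if e.kind in kinds:
            out[node] += 1
    return out


class TestDegree:
    def test_known_compound_degrees(self, network):
        report = network.degree("AC-PT", "left", DIABETES_TARGET_KINDS)
        assert report.degrees["AC3"] == 8  # 6 direct + 2 indirect
        assert report.degrees["AC42"] == 2  # DNA polymerase + topoisomerase 2
        assert report.degrees["AC2"] == 5  # 1 direct + 4 indirect

    def test_degree_extremes_span_one_to_eight(self, network):
        report = network.degree("AC-PT", "left", DIABETES_TARGET_KINDS)
        assert report.min_degree == 1
        assert report.max_degree == 8

    def test_zero_edge_network_all_degrees_zero(self):
        reg = Registry()
        reg.add_node(NodeRecord(code="AC1", kind="compound", name="x"))
        net = LayeredNetwork(reg)
        report = net.degree("AC-PT", "left")
        assert report.degrees == {}
        assert report.min_degree == report.max_degree == 0

    def test_unknown_layer_or_side_is_usage_error(self, network):
        with pytest.raises(UsageError):
            network.degree("AC-XX", "left")
        with pytest.raises(UsageError):
            network.degree("AC-PT", "middle")

    def test_bipartite_handshake_on_every_fixture_layer(self, network):
        for layer in ("ADP-AC", "AC-PT", "PT-P", "PT-D"):
            edges = network.layer_edges(layer)
            left = network.degree(layer, "left")
            right = network.degree(layer, "right")
            assert sum(left.degrees.values()) == len(edges)
            assert sum(right.degrees.values()) == len(edges)

    @pytest.mark.parametrize("seed", range(5))
    def test_handshake_and_oracle_equivalence_on_synthetic(self, seed):
        reg, _ = generate(GeneratorConfig(seed=seed))
        net = LayeredNetwork(reg)
        for layer, kinds in (
            ("AC-PT", DIABETES_TARGET_KINDS),
            ("PT-P", ("participates_in",)),
        ):
            edges = net.layer_edges(layer)
            for side in ("left", "right"):
                engine = net.degree(layer, side, kinds).degrees
                oracle = brute_degree(edges, side, kinds)
                assert engine == oracle


class TestHubs:
    def test_compound_hubs_at_threshold_four(self, network):
        report = network.degree("AC-PT", "left", DIABETES_TARGET_KINDS)
        assert set(hubs(report, 4)) == {"AC2", "AC3", "AC5", "AC6", "AC11"}

    def test_ordering_degree_desc_then_code_asc(self, network):
        report = network.degree("AC-PT", "left", DIABETES_TARGET_KINDS)
        listed = hubs(report, 4)
        assert listed == ["AC3", "AC5", "AC2", "AC11", "AC6"]

    def test_threshold_zero_returns_every_member_node(self, network):
        report = network.degree("AC-PT", "left", DIABETES_TARGET_KINDS)
        assert len(hubs(report, 0)) == len(report.degrees)

    def test_multipathway_targets_are_pathway_hubs(self, network):
        report = network.degree("PT-P", "left")
        assert {"PT14", "PT47", "PT52", "PT56"} <= set(hubs(report, 4))

    def test_hub_monotonicity_in_threshold(self, network):
        report = network.degree("AC-PT", "left", DIABETES_TARGET_KINDS)
        for t in range(0, 9):
            assert set(hubs(report, t + 1)) <= set(hubs(report, t))


class TestCoverage:
    def test_all_plants_cover_everything_when_all_compounds_linked(self):
        reg, truth = generate(GeneratorConfig(seed=11))
        net = LayeredNetwork(reg)
        assert net.coverage_fraction(set(reg.node_codes("plant"))) == 1.0

    def test_planted_cover_recovered(self):
        reg, truth = generate(GeneratorConfig(seed=7))
        net = LayeredNetwork(reg)
        assert net.coverage_fraction(truth.cover_plants) == pytest.approx(
            truth.cover_fraction, abs=0.02
        )

    def test_empty_compound_network_raises(self):
        reg = Registry()
        reg.add_node(NodeRecord(code="ADP1", kind="plant", name="p"))
        with pytest.raises(UsageError):
            LayeredNetwork(reg).coverage_fraction({"ADP1"})

    def test_unknown_plant_code_raises(self, network):
        with pytest.raises(UsageError):
            network.coverage_fraction({"ADP99"})


class TestSharedTargetPartners:
    def test_exclusive_target_compound_has_no_partners(self, network):
        assert network.shared_target_partners("AC6") == {}

    def test_triterpene_pair_shares_three_direct_targets(self, network):
        partners = network.shared_target_partners("AC3")
        assert partners["AC5"] == {"PT9", "PT12", "PT40"}

    def test_compound_with_no_direct_edges_has_no_partners(self, network):
        # AC1 has no compound-target edges at all in the curated set
        assert network.shared_target_partners("AC1") == {}

    def test_partnership_is_symmetric_with_equal_shared_sets(self, network):
        compounds = network.layer_nodes("AC-PT", "left")
        table = {c: network.shared_target_partners(c) for c in compounds}
        for a, partners in table.items():
            for b, shared in partners.items():
                assert table[b][a] == shared
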