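"""Pharmacophore-gated target enrichment: seeds, proposals, idempotence."""

import pytest

from phytoformula import (
    EnrichmentConfig,
    EnrichmentError,
    LayeredNetwork,
    enrich,
    enrich_all,
    find_seeds,
)
from phytoformula.enrichment import (
    STATUS_NO_PARTNER,
    STATUS_REJECTED,
    proposed_targets_for,
)
from phytoformula.synthetic import GeneratorConfig, generate


class TestFindSeeds:
    def test_high_direct_degree_seeds(self, network):
        seeds = find_seeds(network, min_direct_degree=4)
        assert set(seeds) == {"AC3", "AC5", "AC6", "AC11"}

    def test_min_degree_one_selects_all_directly_binding_compounds(self, network):
        seeds = find_seeds(network, min_direct_degree=1)
        report = network.degree("AC-PT", "left", ("targets_direct",))
        assert set(seeds) == {c for c, d in report.degrees.items() if d >= 1}

    def test_matches_brute_force_sort_on_synthetic(self):
        reg, _ = generate(GeneratorConfig(seed=2))
        net = LayeredNetwork(reg)
        counts = {}
        for e in reg.edges:
            if e.kind == "targets_direct":
                counts[e.source] = counts.get(e.source, 0) + 1
        expected = sorted(
            (c for c, d in counts.items() if d >= 2),
            key=lambda c: (-counts[c], int(c[2:])),
        )
        assert find_seeds(net, min_direct_degree=2) == expected


class TestEnrichSingleSeed:
    def test_betulinic_acid_gains_from_oleanolic_rejects_diadzein(
        self, network, profiles, enrichment_config
    ):
        proposals = enrich(network, profiles, "AC3", enrichment_config)
        assert proposed_targets_for(proposals) == {"PT13", "PT25", "PT26"}
        by_partner = {p.partner: p for p in proposals}
        assert by_partner["AC42"].status == STATUS_REJECTED
        assert by_partner["AC42"].proposed_targets == set()

    def test_oleanolic_acid_gains_from_betulinic_rejects_gallic(
        self, network, profiles, enrichment_config
    ):
        proposals = enrich(network, profiles, "AC5", enrichment_config)
        assert proposed_targets_for(proposals) == {"PT38", "PT11", "PT60"}
        by_partner = {p.partner: p for p in proposals}
        assert by_partner["AC11"].status == STATUS_REJECTED

    def test_exclusive_compound_yields_single_no_partner_record(
        self, network, profiles, enrichment_config
    ):
        proposals = enrich(network, profiles, "AC6", enrichment_config)
        assert len(proposals) == 1
        assert proposals[0].status == STATUS_NO_PARTNER
        assert proposed_targets_for(proposals) == set()

    def test_proposals_never_overlap_known_direct_targets(
        self, network, profiles, enrichment_config
    ):
        for seed in find_seeds(network, min_direct_degree=4):
            own = network.direct_targets(seed)
            for p in enrich(network, profiles, seed, enrichment_config):
                assert p.proposed_targets.isdisjoint(own)
                if p.partner is not None:
                    assert len(p.shared_targets) >= 1

    def test_seed_without_structure_raises(self, network, profiles, enrichment_config):
        missing = {k: v for k, v in profiles.items() if k != "AC3"}
        with pytest.raises(EnrichmentError):
            enrich(network, missing, "AC3", enrichment_config)


class TestEnrichAll:
    def test_gallic_acid_gains_three_targets(self, network, profiles, enrichment_config):
        enriched, _ = enrich_all(network, profiles, enrichment_config)
        gained = {
            e.target for e in enriched.edges
            if e.kind == "targets_enriched" and e.source == "AC11"
        }
        assert gained == {"PT53", "PT21", "PT3"}

    def test_original_network_untouched(self, network, profiles, enrichment_config):
        before = network.registry.edge_keys()
        enrich_all(network, profiles, enrichment_config)
        assert network.registry.edge_keys() == before

    def test_empty_seed_list_is_identity(self, network, profiles, enrichment_config):
        enriched, log = enrich_all(network, profiles, enrichment_config, seeds=[])
        assert enriched.edge_keys() == network.registry.edge_keys()
        assert log == []

    def test_idempotence_no_duplicate_edges_on_second_run(
        self, network, profiles, enrichment_config
    ):
        enriched1, _ = enrich_all(network, profiles, enrichment_config)
        net1 = LayeredNetwork(enriched1)
        enriched2, _ = enrich_all(net1, profiles, enrichment_config)
        assert sorted(e.key for e in enriched2.edges) == sorted(
            e.key for e in enriched1.edges
        )

    def test_counterfactual_removing_shared_target_removes_proposal(
        self, registry, profiles, enrichment_config
    ):
        # drop the only shared direct target between AC11 and kaempferol
        pruned = registry.copy()
        pruned.edges = [
            e for e in pruned.edges
            if not (e.source == "AC7" and e.target == "PT16" and e.kind == "targets_direct")
        ]
        net = LayeredNetwork(pruned)
        enriched, _ = enrich_all(net, profiles, enrichment_config)
        gained = {
            e.target for e in enriched.edges
            if e.kind == "targets_enriched" and e.source == "AC11"
        }
        assert "PT53" not in gained  # kaempferol's lipoxygenase no longer propagates
        assert gained == {"PT21", "PT3"}

    def test_proposal_filter_vetoes(self, network, profiles, enrichment_config):
        config = EnrichmentConfig(
            similarity_threshold=enrichment_config.similarity_threshold,
            proposal_filter=lambda p: False,  # external docking veto
        )
        enriched, log = enrich_all(network, profiles, config)
        assert all(e.kind != "targets_enriched" for e in enriched.edges)
        assert all(p.status != "proposed" or p.proposed_targets == set() for p in log)
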