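#!/usr/bin/env python
"""Target enrichment of the multi-target seed compounds.

Applies the similarity-gated propagation rule to every compound with at
least four direct protein targets and reports the proposed new targets
per seed, the rejected (feature-dissimilar) partners, and the enriched
network export.
"""

import json
from pathlib import Path

from phytoformula import (
    EnrichmentConfig,
    LayeredNetwork,
    enrich_all,
    export_network,
    find_seeds,
    load_default_config,
    load_fixture,
    profile_table,
)
from phytoformula.registry import code_key

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

registry, structures = load_fixture()
network = LayeredNetwork(registry)
profiles = profile_table(structures)
threshold = float(load_default_config()["similarity_threshold"])

seeds = find_seeds(network, min_direct_degree=4)
print(f"seeds (>= 4 direct targets): {seeds}")

enriched, proposals = enrich_all(
    network, profiles, EnrichmentConfig(similarity_threshold=threshold)
)
gained: dict[str, list[str]] = {}
for e in enriched.edges:
    if e.kind == "targets_enriched":
        gained.setdefault(e.source, []).append(e.target)
for seed in seeds:
    targets = sorted(gained.get(seed, []), key=code_key)
    names = [registry.nodes[t].name for t in targets]
    print(f"  {seed} ({registry.nodes[seed].name}): +{targets} {names}")

rejected = [p.to_dict() for p in proposals if p.status == "rejected_dissimilar"]
print(f"{len(rejected)} partner pairings rejected by the similarity gate")

export_network(enriched, "edge-tsv", OUT / "enriched_edges.tsv")
(OUT / "enrichment.json").write_text(
    json.dumps([p.to_dict() for p in proposals], indent=2) + "\n"
)
print(f"wrote {OUT / 'enrichment.json'} and enriched_edges.tsv")
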