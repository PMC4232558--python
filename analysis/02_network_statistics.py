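#!/usr/bin/env python
"""Degree and hub statistics of the four network layers.

Finds the multi-target compounds (disease-target degree >= 4), the
multi-pathway proteins, the degree extremes of the compound-target layer
(min 1, max 8) and the shared-target partner structure used later by
target enrichment.
"""

import json
from pathlib import Path

from phytoformula import LayeredNetwork, hubs, load_fixture
from phytoformula.registry import DIABETES_TARGET_KINDS, code_key

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

registry, _ = load_fixture()
network = LayeredNetwork(registry)

report = network.degree("AC-PT", "left", DIABETES_TARGET_KINDS)
print(f"compound-target layer: {len(report.degrees)} connected compounds, "
      f"degree min {report.min_degree} / max {report.max_degree}")

compound_hubs = hubs(report, 4)
print(f"multi-target hub compounds (degree >= 4): {compound_hubs}")

pw = network.degree("PT-P", "left")
pathway_hubs = hubs(pw, 4)
print(f"multi-pathway proteins (pathway degree >= 4): {pathway_hubs}")

target_side = network.degree("AC-PT", "right", ("targets_direct",))
popular = hubs(target_side, 3)
print(f"proteins bound by >= 3 compounds: {popular}")

partners = {
    c: {p: sorted(s, key=code_key) for p, s in network.shared_target_partners(c).items()}
    for c in network.layer_nodes("AC-PT", "left")
}
partners = {c: p for c, p in partners.items() if p}

payload = {
    "ac_pt_degrees": report.degrees,
    "compound_hubs_threshold_4": compound_hubs,
    "multipathway_proteins": pathway_hubs,
    "popular_direct_targets": popular,
    "shared_target_partners": partners,
}
(OUT / "network_statistics.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
print(f"wrote {OUT / 'network_statistics.json'}")
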