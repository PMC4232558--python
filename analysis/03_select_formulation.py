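#!/usr/bin/env python
"""Threshold-degree ideal-formulation selection.

Runs the selection at thresholds 4/4 twice — once with the curated
multi-pathway protein set supplied as an override, once deriving it from
the packaged target-pathway layer — and reports the seven-compound ideal
formulation together with its full trace.
"""

import json
from pathlib import Path

from phytoformula import FormulationConfig, LayeredNetwork, ideal_formulation, load_fixture
from phytoformula.registry import code_key

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

registry, _ = load_fixture()
network = LayeredNetwork(registry)

override = frozenset({"PT14", "PT47", "PT52", "PT56"})
with_override = ideal_formulation(network, FormulationConfig(pt_p_override=override))
derived = ideal_formulation(network, FormulationConfig())

print("ideal formulation (curated multi-pathway set):",
      sorted(with_override.ideal_formulation, key=code_key))
print("ideal formulation (derived from PT-P layer):  ",
      sorted(derived.ideal_formulation, key=code_key))
print("multi-target compounds AC_PT:", sorted(with_override.ac_pt, key=code_key))
print("best binder per multi-pathway protein:", with_override.ac_ptp)
agree = with_override.ideal_formulation == derived.ideal_formulation
print(f"override and derived selections agree: {agree}")

(OUT / "formulation.json").write_text(
    json.dumps({"with_override": with_override.to_dict(),
                "derived": derived.to_dict()}, indent=2) + "\n"
)
print(f"wrote {OUT / 'formulation.json'}")
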