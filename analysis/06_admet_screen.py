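#!/usr/bin/env python
"""Drug-likeness screen of the formulation and enrichment compounds.

Computes MW, donor/acceptor counts, Crippen logP and rule-of-five
violations for every packaged structure, applies the published acceptance
windows (MW 130-725, logP -2.0..6.5) and reports the violation range.
"""

from pathlib import Path

from phytoformula import load_default_config, load_fixture
from phytoformula.admet import screen_table
from phytoformula.registry import code_key

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

_, structures = load_fixture()
windows = {k: tuple(v) for k, v in load_default_config()["adme_windows"].items()}
records = screen_table(structures, windows=windows)

lines = ["code\tmw\tdonors\tacceptors\tlogp\tviolations\twindow_flags"]
for r in sorted(records, key=lambda r: code_key(r.code)):
    flags = ";".join(f"{k}={v}" for k, v in sorted(r.window_flags.items()))
    lines.append(f"{r.code}\t{r.mw:.2f}\t{r.donors}\t{r.acceptors}\t"
                 f"{r.logp:.3f}\t{r.violations}\t{flags}")
(OUT / "adme.tsv").write_text("\n".join(lines) + "\n")

print(f"screened {len(records)} structures")
print(f"  MW range: {min(r.mw for r in records):.1f} - {max(r.mw for r in records):.1f} Da")
print(f"  rule-of-five violations: {min(r.violations for r in records)}"
      f" - {max(r.violations for r in records)}")
out_of_window = [r.code for r in records if "out" in r.window_flags.values()]
print(f"  compounds outside an acceptance window: {out_of_window or 'none'}")
print(f"wrote {OUT / 'adme.tsv'}")
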