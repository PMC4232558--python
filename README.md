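# phytoformula

Network pharmacology for multi-herb formulation design.

Traditional anti-diabetic treatment uses combined plant extracts, but with
dozens of candidate plants, each contributing many phytochemicals acting
on many proteins, choosing *which* compounds actually matter is the hard
part. `phytoformula` implements a transparent, fully-traceable pipeline
for that decision over a layered network of medicinal **plants** (`ADP`),
their **active compounds** (`AC`), the compounds' **protein targets**
(`PT`, split into direct binding and indirect influence), and the
targets' **pathways** (`P`) and **diseases** (`D`):

1. **Registry & network** — typed, validated node/edge tables with
   evidence anchors on every edge; SIF/GraphML/TSV export.
2. **Formulation selection** — with `x_i` the disease-target degree of
   compound *i* and `y_j` the pathway degree of protein *j*, select
   `AC_PT = {i : x_i ≥ 4}` (multi-target compounds),
   `PT_P = {j : y_j ≥ 4}` (multi-pathway proteins), the highest-degree
   binder `AC{PT_P(j)}` of each multi-pathway protein, and the ideal
   formulation `IF = AC_PT ∪ {AC{PT_P(j)}}`.
3. **Pharmacophore profiling** — six feature classes (acceptor, donor,
   hydrophobe, ±ionizable, aromatic ring) counted by a versioned SMARTS
   rule table; pair similarity by count-vector Tanimoto
   `Σmin/Σmax`, with a verdict threshold calibrated on labeled pairs.
4. **Target enrichment** — for each multi-target seed compound, propagate
   the direct targets of feature-similar partners that share at least one
   directly-bound protein; dissimilar partners are rejected with full
   provenance; a filter hook accepts external (e.g. docking) vetoes.
5. **Drug-likeness screen** — MW, H-bond donors/acceptors, Crippen logP,
   Lipinski rule-of-five violation counts, and configurable acceptance
   windows.
6. **Synthetic networks** — a seeded generator producing study-shaped
   registries with planted hubs, multi-pathway proteins and plant covers,
   plus recorded ground truth, so every selection rule is testable
   without any database access.

A curated in-repo fixture freezes the study network (29 plants, 57
compounds, 65 targets, 44 pathways; 114 text-attested edges; SMILES for
the 25 formulation/enrichment compounds). See `docs/methods.md` for the
model, assumptions and limitations.

## Worked example

```python
from phytoformula import (
    LayeredNetwork, FormulationConfig, ideal_formulation, load_fixture,
    profile_table, enrich_all, EnrichmentConfig, load_default_config,
)

registry, structures = load_fixture()
network = LayeredNetwork(registry)

result = ideal_formulation(network, FormulationConfig())
print(sorted(result.ideal_formulation))
# ['AC11', 'AC2', 'AC3', 'AC5', 'AC54', 'AC58', 'AC6']

profiles = profile_table(structures)
threshold = load_default_config()["similarity_threshold"]   # 0.2436
enriched, log = enrich_all(network, profiles,
                           EnrichmentConfig(similarity_threshold=threshold))
print(sorted(e.target for e in enriched.edges
             if e.kind == "targets_enriched" and e.source == "AC5"))
# ['PT11', 'PT38', 'PT60']
```

The selection finds the seven-compound ideal formulation — the five
multi-target hubs (1-deoxynojirimycin, betulinic acid, oleanolic acid,
myricetin, gallic acid; disease-target degrees 5, 8, 6, 4, 5) plus
shogaol and wedelolactone, each the sole binder of a multi-pathway
protein. Enrichment then proposes three new binding targets for oleanolic
acid (5-alpha reductase, DNA topoisomerase 2, LXR alpha), propagated from
betulinic acid (similarity 1.0) while its feature-dissimilar partner
gallic acid (similarity 0.154, below the 0.244 gate) is rejected.

Or from the shell:

```bash
phytoformula validate                 # check the packaged fixture
phytoformula formulate                # JSON formulation report with trace
phytoformula hubs --layer AC-PT --side compound --threshold 4
phytoformula enrich --min-direct-degree 4
phytoformula adme                     # drug-likeness TSV
phytoformula simulate --seed 1 --out sim/   # synthetic registry
phytoformula run --out run/           # full pipeline with artifacts
```

The numbered scripts under `analysis/` run the same stages as narrative
drivers and write their tables under `results/`.

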