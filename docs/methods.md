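# Methods

## The model

`phytoformula` operates on a typed five-kind node registry — medicinal
plants (`ADP`), active phytochemicals (`AC`), protein targets (`PT`),
biochemical pathways (`P`), diseases (`D`) — joined by six relation kinds:
`contains` (plant → compound), `targets_direct` (compound binds protein),
`targets_indirect` (compound influences a protein's activity or expression
without reported binding), `targets_nondiabetic` (interaction outside the
disease of interest), `participates_in` (protein → pathway) and
`implicated_in` (protein → disease). A seventh kind, `targets_enriched`,
is reserved for interactions the enrichment procedure predicts, so
predicted edges can never be confused with curated ones.

The registry is viewed as four bipartite layers (ADP-AC, AC-PT, PT-P,
PT-D). All analytics reduce to *degree*: the number of neighbours a node
has in a layer, counting a configurable subset of edge kinds.

### Formulation selection

Write `x_i` for the disease-target degree of compound *i* (direct +
indirect edges by default; `targets_nondiabetic` is always excluded from
selection) and `y_j` for the pathway degree of protein *j*. With
compound threshold `x*` and pathway threshold `y*` (both default 4):

- `AC_PT = { i : x_i ≥ x* }` — the multi-target compounds;
- `PT_P  = { j : y_j ≥ y* }` — the multi-pathway proteins;
- `AC{PT_P(j)}` — for each `j ∈ PT_P`, the binder of `j` with maximal
  `x_i`; argmax ties break to the lowest compound code and all tied
  candidates remain visible in the trace;
- ideal formulation `IF = AC_PT ∪ { AC{PT_P(j)} }`.

`IF` is anti-monotone in both thresholds, and every member is justified
by its trace entry (degree ≥ `x*`, or chosen binder of some multi-pathway
protein). `PT_P` may be supplied as an explicit override set for the case
where multi-pathway membership is a curated assertion rather than
derivable from a complete PT-P edge list; on the packaged fixture the
override and the derived set coincide (the fixture pads the PT-P layer —
see below).

The default thresholds of 4 come from inspecting the degree range of the
curated AC-PT layer (min 1, max 8) and choosing the midpoint as the
"many targets / many pathways" cut; they are configuration, not code.

### Pharmacophore profiles and similarity

Each structure is typed into six classical feature classes — H-bond
acceptor (A), donor (D), hydrophobic (H), negatively ionizable (N),
positively ionizable (P), aromatic ring (R) — by a versioned SMARTS rule
table shipped as data (`pharmacophore_rules.yaml`). A and D follow
Lipinski-style definitions (N/O atoms; N-H/O-H atoms). H counts
non-aromatic carbons with no bonded heteroatom, so a triterpene skeleton
contributes in proportion to its bulk. N and P are ionization states
expected at pH 7 (acid groups; aliphatic amines). R is the aromatic ring
count under RDKit's default aromaticity perception.

Similarity between count vectors `a`, `b` is the Tanimoto coefficient
`Σ_c min(a_c,b_c) / Σ_c max(a_c,b_c)`: symmetric, in [0, 1], 1 for
identical non-empty profiles, undefined (an error) for two all-zero
profiles.

This is a deliberate, alignment-free simplification of 3D pharmacophore
alignment. Its contract is *ordering*, not absolute score: on the curated
labeled pairs (the two pentacyclic triterpene acids; the two
4',7-dihydroxyisoflavones; all 45 pairs among the ten aldose-reductase
binders; versus triterpene-isoflavone and triterpene-gallic-acid
counter-pairs) every similar pair must score strictly above every
dissimilar pair. Under rule table v1 the lowest similar pair scores
0.3333 (astragalin vs perilloside A — the glycosides) and the highest
dissimilar pair 0.1538 (oleanolic vs gallic acid). The verdict threshold
is the midpoint, 0.2436, stored in `default_config.yaml` with its
provenance and recomputable via `calibrate_threshold`.

Known limitation: the metric sees only global feature counts, so "partial
similarity" (two compounds sharing one substructural region) appears only
as an intermediate score, and some pairs the original analysis called
dissimilar by shape (e.g. a furanocoumarin vs an isoflavone, both small
tri-aromatic acceptors) score moderately high. None of these pairs can
propagate a target in the curated network, but the caveat matters for new
data.

### Target enrichment

Seeds are compounds with ≥ 4 *direct* targets (only binding interactions
are propagated). For each partner compound sharing ≥ 1 direct target with
the seed: if the pair passes the similarity gate, the partner's remaining
direct targets are proposed for the seed; otherwise the pairing is logged
`rejected_dissimilar`. Seeds with no partner produce a single
`no_partner` record. `enrich_all` adds accepted proposals to a copy of
the registry as `targets_enriched` edges — never duplicating an existing
edge, hence idempotent — and returns the full proposal log.

The original procedure confirmed each proposal by docking; that step is
out of scope here and is represented by the `proposal_filter` callback in
`EnrichmentConfig`, through which an external docking score can veto
proposals. An optional `proportional_cap` mode limits the number of
propagated targets in proportion to the similarity score ("the higher the
similarity, the more targets shared"); it is off by default because no
quantitative propagation rule is established. The gate is symmetric;
receptor-side effects that make propagation asymmetric in reality (a
small binding pocket admitting a small acid but not a bulky triterpene)
are not modelled.

### Drug-likeness screen

MW from RDKit atomic masses; logP by the Wildman-Crippen atom-contribution
method; donors/acceptors from the same rule table as the profiler, so the
two screens cannot disagree on what a donor is. Rule-of-five violations:
+1 each for MW > 500, logP > 5, donors > 5, acceptors > 10. The window
screen flags each property against `[lo, hi]` acceptance ranges
(defaults: MW 130–725, logP −2.0–6.5); properties this package does not
compute (Caco-2, MDCK, logS, % oral absorption) accept externally
supplied values or are flagged `not_evaluated` — no open specification
exists for the proprietary predictors, so re-implementing them was
rejected. Crippen logP differs from proprietary logP estimates;
accordingly only the violation bound (≤ 2 across the fixture) is asserted,
not per-compound logP values.

## The curated fixture

The node registries are transcribed verbatim from the study's code
tables: 29 plants, 57 compounds (codes AC1–AC60 with AC8/AC28/AC29
absent), 65 targets (PT1–PT72 with seven gaps), 44 pathways (P1–P48 with
P15/P16/P17/P39 absent). Gaps are preserved, never renumbered. Disease
nodes carry a `D` prefix coined by this package.

Edges are only those attested in prose or figure captions, each tagged
with its anchor (e.g. `Discussion-AC3`, `Fig8-caption`); the full
original networks exist only as figures and are *not* reconstructed, so
the fixture is a documented subset (114 edges). Three flagged exceptions:

- `synthetic-padding` PT-P edges give the four curated multi-pathway
  proteins (PT14, PT47, PT52, PT56) pathway degree ≥ 4 so they are
  derivable from the layer as well as assertable via the override; no
  other protein is padded to the threshold.
- two `curated-assumption` AC-PT edges (kaempferol → lipoxygenase,
  apigenin → 20-alpha-HSD) resolve which of the three flavones
  contributes which enriched target of gallic acid — the source text
  names the three targets but not the per-compound attribution (the
  luteolin → alpha-glucosidase edge is caption-attested).
- shogaol's COX-2 and MAPK interactions are typed `targets_indirect`
  (they are expression-level effects), which is also why shogaol is no
  compound's enrichment partner.

SMILES for the 25 formulation/enrichment compounds are compiled from the
standard chemical identity of the named compounds and frozen in
`structures.csv` with a provenance column. Beta glucan (AC60), a polymer
with no defined monomer count, has no structure and is excluded from
profiling and the ADME screen. A frozen manifest
(`fixture_manifest.json`) guards the fixture's shape against silent
edits.

## The synthetic generator

`synthetic.generate` draws registries with the statistical shape of the
curated network, with defaults fixed to the study conditions: 29/57/65/44
nodes per kind; five planted hub compounds with disease-target degrees
(8, 6, 5, 5, 4) and non-hub degrees drawn from {1: 0.60, 2: 0.25,
3: 0.15} (so the compound-degree support is exactly 1..8 and the hub set
is recoverable by construction); four planted multi-pathway proteins at
pathway degree ≥ 4 with all others capped below; eight cover plants
jointly covering 70 % of compounds; a 60/40 direct/indirect edge split
with a reserved 10 % pool of non-disease targets receiving
`targets_nondiabetic` edges. Ground truth (hubs, multi-pathway proteins,
cover, expected IF) is recorded at generation time by direct enumeration
of the emitted edge list, so selector outputs are checked against
construction, not against themselves. The same seed reproduces the
identical registry byte-for-byte through `write_registry_dir`.

What the generator does *not* emulate: correlated plant-compound
chemistry (compounds are assigned to plants at random), compound
structures (synthetic registries carry no SMILES, so enrichment is only
exercised on the curated fixture), and hub/target popularity correlation.
Passing recovery tests therefore demonstrates correctness of the
selection algebra under the assumed degree structure, not robustness of
the curation itself.

## Numerical and design choices

- All orderings are deterministic: (degree desc, code asc) with natural
  numeric code order (AC2 before AC11); exports sort edges by
  (source, target, kind).
- Degree over an empty layer reports min = max = 0; layer membership is
  incidence to any edge of the layer, so a compound whose only edges are
  filtered out reports degree 0 rather than disappearing.
- Coverage of an empty compound set is an error (division guard), as is a
  similarity between two featureless profiles and an acceptance window
  with lo > hi.
- Validation is total and categorized: parse errors carry line numbers,
  duplicate codes name the code, schema errors name the incompatible
  kinds.
- Analysis problem sizes: property checks run on 100 seeded generator
  draws (each ~29+57+65+44 nodes, ~300 edges), which exercises every
  selection path while keeping the full suite in a few seconds.

## Reproducibility surfaces

`tests/` pins the worked examples (the seven-compound formulation, the
five hubs, the four enrichment outcomes, the degree extremes, the ADME
bounds) and the structural invariants (bipartite handshake, threshold
anti-monotonicity, enrichment idempotence, similarity symmetry/range,
graph round-trips, degree-oracle equivalence, planted-structure
recovery). `scripts/acceptance.py` recomputes the headline degree and
ADME quantities from scratch and refuses to report if planted-structure
recovery fails at the requested seed.
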