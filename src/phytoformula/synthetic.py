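"""Random multi-layer networks with planted, recorded ground truth.

The generator emits registries with the same statistical shape as the
curated study network: a plant-compound layer in which a small group of
"cover" plants accounts for a fixed fraction of all compounds; a
compound-target layer whose compound degrees span 1..8 with a handful of
planted multi-target hub compounds and a majority of single- or few-target
compounds, edges split between direct binding, indirect influence and
non-disease interactions; a target-pathway layer with a small planted set
of multi-pathway proteins; and a target-disease layer.

Everything planted (hub compounds, multi-pathway proteins, the plant
cover, the expected ideal-formulation set) is recorded in a
:class:`GroundTruth` computed at generation time by direct enumeration of
the emitted edge list, so selector outputs can be checked against
construction rather than against themselves.  The same seed always
produces the identical registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .registry import NodeRecord, Registry, TypedEdge


@dataclass
class GeneratorConfig:
    """Study-shaped defaults: sizes and degree structure of the curated network."""

    n_plants: int = 29
    n_compounds: int = 57
    n_targets: int = 65
    n_pathways: int = 44
    n_diseases: int = 8
    #: planted multi-target hub compounds; the study's five hubs have
    #: disease-target degrees 8, 6, 5, 5 and 4 (min 1 / max 8 overall)
    hub_degrees: tuple[int, ...] = (8, 6, 5, 5, 4)
    #: degree distribution for non-hub compounds (must stay below the
    #: compound threshold so the planted hub set is exactly recoverable)
    nonhub_degree_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.60, 2: 0.25, 3: 0.15}
    )
    compound_threshold: int = 4
    pathway_threshold: int = 4
    n_multipathway_targets: int = 4
    #: probability that a bound target participates in at least one pathway
    p_target_in_pathway: float = 0.7
    #: fraction of targets reserved as non-disease (dash-line) targets
    nondiabetic_target_fraction: float = 0.1
    #: per-compound probability of one extra non-disease edge
    nondiabetic_edge_rate: float = 0.2
    #: probability a disease-target edge is direct binding (else indirect)
    p_direct: float = 0.6
    #: planted plant cover: n_cover_plants cover cover_fraction of compounds
    n_cover_plants: int = 8
    cover_fraction: float = 0.70
    p_target_disease: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.cover_fraction, self.nondiabetic_target_fraction,
                 self.nondiabetic_edge_rate, self.p_direct,
                 self.p_target_in_pathway, self.p_target_disease)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigError("all fractions/probabilities must lie in [0, 1]")
        if abs(sum(self.nonhub_degree_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("nonhub degree weights must sum to 1")
        n_disease_targets = self.n_targets - int(
            round(self.nondiabetic_target_fraction * self.n_targets)
        )
        if self.hub_degrees and max(self.hub_degrees) > n_disease_targets:
            raise ConfigError(
                f"hub degree {max(self.hub_degrees)} exceeds the "
                f"{n_disease_targets} available disease targets"
            )
        if max(self.nonhub_degree_weights) >= self.compound_threshold:
            raise ConfigError("non-hub degrees must stay below the compound threshold")
        if self.pathway_threshold + 2 > self.n_pathways:
            raise ConfigError("not enough pathways for the planted multi-pathway degrees")
        if len(self.hub_degrees) + 1 > self.n_compounds:
            raise ConfigError("more planted hubs than compounds")


@dataclass
class GroundTruth:
    hub_compounds: set[str]
    multipathway_targets: set[str]
    cover_plants: set[str]
    cover_fraction: float
    expected_ac_ptp: dict[str, str]
    expected_if: set[str]
    compound_degrees: dict[str, int]


def _codes(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(1, n + 1)]


def generate(config: GeneratorConfig | None = None) -> tuple[Registry, GroundTruth]:
    """Draw one synthetic registry plus its ground truth."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    registry = Registry()
    plants = _codes("ADP", config.n_plants)
    compounds = _codes("AC", config.n_compounds)
    targets = _codes("PT", config.n_targets)
    pathways = _codes("P", config.n_pathways)
    diseases = _codes("D", config.n_diseases)
    for kind, codes in (
        ("plant", plants), ("compound", compounds), ("target", targets),
        ("pathway", pathways), ("disease", diseases),
    ):
        for code in codes:
            registry.add_node(NodeRecord(code=code, kind=kind, name=f"synthetic {code}"))

    # --- partition targets into disease / non-disease pools ---------------
    n_nondiab = int(round(config.nondiabetic_target_fraction * config.n_targets))
    shuffled_targets = list(rng.permutation(targets))
    nondiab_pool = shuffled_targets[:n_nondiab]
    diab_pool = shuffled_targets[n_nondiab:]

    # --- compound-target layer with planted hub degrees -------------------
    hub_list = [str(c) for c in rng.choice(compounds, size=len(config.hub_degrees), replace=False)]
    degrees: dict[str, int] = {}
    support = sorted(config.nonhub_degree_weights)
    weights = [config.nonhub_degree_weights[k] for k in support]
    # guarantee the configured minimum degree is realised
    nonhubs = [c for c in compounds if c not in hub_list]
    for compound, deg in zip(hub_list, config.hub_degrees):
        degrees[compound] = int(deg)
    drawn = rng.choice(support, size=len(nonhubs), p=weights)
    for compound, deg in zip(nonhubs, drawn):
        degrees[compound] = int(deg)
    if nonhubs and min(support) not in drawn:
        degrees[nonhubs[0]] = min(support)

    ct_edges: list[TypedEdge] = []
    for compound in compounds:
        chosen = rng.choice(diab_pool, size=degrees[compound], replace=False)
        for target in chosen:
            kind = "targets_direct" if rng.random() < config.p_direct else "targets_indirect"
            ct_edges.append(TypedEdge(compound, str(target), kind, "synthetic"))
        if nondiab_pool and rng.random() < config.nondiabetic_edge_rate:
            target = str(rng.choice(nondiab_pool))
            ct_edges.append(TypedEdge(compound, target, "targets_nondiabetic", "synthetic"))

    # --- target-pathway layer with planted multi-pathway targets ----------
    bound_targets = sorted({e.target for e in ct_edges if e.kind != "targets_nondiabetic"})
    n_mp = min(config.n_multipathway_targets, len(bound_targets))
    mp_targets = [str(t) for t in rng.choice(bound_targets, size=n_mp, replace=False)]
    tp_edges: list[TypedEdge] = []
    for target in bound_targets:
        if target in mp_targets:
            deg = int(rng.integers(config.pathway_threshold, config.pathway_threshold + 3))
        elif rng.random() < config.p_target_in_pathway:
            deg = int(rng.integers(1, config.pathway_threshold))
        else:
            continue
        for pathway in rng.choice(pathways, size=deg, replace=False):
            tp_edges.append(TypedEdge(target, str(pathway), "participates_in", "synthetic"))

    # --- target-disease layer ---------------------------------------------
    td_edges: list[TypedEdge] = []
    for target in bound_targets:
        if rng.random() < config.p_target_disease:
            for disease in rng.choice(diseases, size=int(rng.integers(1, 3)), replace=False):
                td_edges.append(TypedEdge(target, str(disease), "implicated_in", "synthetic"))

    # --- plant-compound layer with a planted cover -------------------------
    cover_plants = [str(p) for p in rng.choice(plants, size=config.n_cover_plants, replace=False)]
    other_plants = [p for p in plants if p not in cover_plants]
    n_covered = int(round(config.cover_fraction * config.n_compounds))
    covered = [str(c) for c in rng.choice(compounds, size=n_covered, replace=False)]
    pc_edges: list[TypedEdge] = []
    for compound in compounds:
        pool = cover_plants if compound in covered else other_plants
        n_edges = int(rng.integers(1, min(3, len(pool) + 1)))
        for plant in rng.choice(pool, size=n_edges, replace=False):
            pc_edges.append(TypedEdge(str(plant), compound, "contains", "synthetic"))

    for edge in pc_edges + ct_edges + tp_edges + td_edges:
        registry.add_edge(edge)
    registry.validate()

    # --- ground truth by direct enumeration of the emitted edges ----------
    diab_deg: dict[str, int] = {c: 0 for c in compounds}
    binders: dict[str, list[str]] = {}
    for e in ct_edges:
        if e.kind in ("targets_direct", "targets_indirect"):
            diab_deg[e.source] += 1
            binders.setdefault(e.target, []).append(e.source)
    expected_ac_ptp: dict[str, str] = {}
    for target in mp_targets:
        cands = binders.get(target, [])
        if cands:
            expected_ac_ptp[target] = min(
                cands, key=lambda c: (-diab_deg[c], int(c[2:]))
            )
    truth = GroundTruth(
        hub_compounds=set(hub_list),
        multipathway_targets=set(mp_targets),
        cover_plants=set(cover_plants),
        cover_fraction=n_covered / config.n_compounds,
        expected_ac_ptp=expected_ac_ptp,
        expected_if=set(hub_list) | set(expected_ac_ptp.values()),
        compound_degrees=diab_deg,
    )
    return registry, truth


def write_registry_dir(registry: Registry, outdir) -> None:
    """Emit a registry as the TSV table set the fixture loader reads."""
    from pathlib import Path

    from .registry import code_key, group_edges_by_kind

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kind_file = {
        "plant": "plants.tsv", "compound": "compounds.tsv", "target": "targets.tsv",
        "pathway": "pathways.tsv", "disease": "diseases.tsv",
    }
    for kind, fname in kind_file.items():
        lines = ["code\tname\taliases"]
        for code in registry.node_codes(kind):
            node = registry.nodes[code]
            lines.append(f"{node.code}\t{node.name}\t{'|'.join(node.aliases)}")
        (outdir / fname).write_text("\n".join(lines) + "\n", encoding="utf-8")

    grouped = group_edges_by_kind(registry.edges)
    edge_files = {
        "edges_plant_compound.tsv": ("contains",),
        "edges_compound_target.tsv": (
            "targets_direct", "targets_indirect", "targets_nondiabetic", "targets_enriched",
        ),
        "edges_target_pathway.tsv": ("participates_in",),
        "edges_target_disease.tsv": ("implicated_in",),
    }
    for fname, kinds in edge_files.items():
        edges = [e for k in kinds for e in grouped.get(k, [])]
        edges.sort(key=lambda e: (code_key(e.source), code_key(e.target), e.kind))
        lines = ["source\ttarget\tkind\tevidence"]
        lines += [f"{e.source}\t{e.target}\t{e.kind}\t{e.evidence}" for e in edges]
        (outdir / fname).write_text("\n".join(lines) + "\n", encoding="utf-8")
    (outdir / "structures.csv").write_text("code,name,smiles,provenance\n", encoding="utf-8")
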