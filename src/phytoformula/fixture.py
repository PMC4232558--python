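"""Packaged curated network fixture.

The fixture freezes the study's node registries verbatim (29 plants, 57
active compounds, 65 protein targets, 44 pathways — code gaps preserved,
never renumbered) together with every compound-target, target-pathway,
plant-compound and target-disease edge that is attested in the prose or
figure captions, each tagged with its evidence anchor.  The full networks
of the original figures were never tabulated, so this edge set is a
documented subset; a few target-pathway edges are flagged
``synthetic-padding`` (they make the four curated multi-pathway proteins
derivable from the layer rather than only assertable) and two
compound-target edges are flagged ``curated-assumption``.

Structures (SMILES) are packaged for the formulation and enrichment
compounds, compiled from the standard chemical identity of the named
compounds; beta glucan, a polymer without a defined monomer count, has no
structure entry.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

from .registry import Registry, parse_edge_table, parse_node_table

_NODE_TABLES = (
    ("plants.tsv", "plant"),
    ("compounds.tsv", "compound"),
    ("targets.tsv", "target"),
    ("pathways.tsv", "pathway"),
    ("diseases.tsv", "disease"),
)
_EDGE_TABLES = (
    "edges_plant_compound.tsv",
    "edges_compound_target.tsv",
    "edges_target_pathway.tsv",
    "edges_target_disease.tsv",
)


def data_path(name: str) -> Path:
    return Path(str(resources.files("phytoformula") / "data" / name))


def load_fixture(data_dir: str | Path | None = None) -> tuple[Registry, dict[str, str]]:
    """Load the curated registry and the structure table.

    Returns ``(registry, structures)`` where ``structures`` maps compound
    code to SMILES.  ``data_dir`` overrides the packaged data directory
    (it must contain the same table files).
    """
    base = Path(data_dir) if data_dir is not None else None

    def path_of(name: str) -> Path:
        return (base / name) if base is not None else data_path(name)

    registry = Registry()
    for fname, kind in _NODE_TABLES:
        for record in parse_node_table(path_of(fname), kind):
            registry.add_node(record)
    for fname in _EDGE_TABLES:
        for edge in parse_edge_table(path_of(fname), registry):
            registry.edges.append(edge)
    registry.validate()
    return registry, load_structures(path_of("structures.csv"))


def load_structures(path: str | Path | None = None) -> dict[str, str]:
    """Compound code -> SMILES from a structure CSV (code, name, smiles)."""
    path = Path(path) if path is not None else data_path("structures.csv")
    with open(path, encoding="utf-8") as fh:
        return {row["code"]: row["smiles"] for row in csv.DictReader(fh)}


def load_manifest() -> dict:
    """Frozen fixture statistics used as a regression guard."""
    return json.loads(data_path("fixture_manifest.json").read_text(encoding="utf-8"))
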