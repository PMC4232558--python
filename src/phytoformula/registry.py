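"""Node registries and typed edge tables.

The data model is a coded multi-layer pharmacology network: medicinal
plants (``ADP``), their active phytochemicals (``AC``), the proteins those
compounds act on (``PT``), the biochemical pathways the proteins take part
in (``P``) and the diseases they are implicated in (``D``).  Edges are
typed: a plant *contains* a compound; a compound *targets* a protein
directly (binding), indirectly (influence on activity or expression) or
outside the disease of interest; a protein *participates in* a pathway and
is *implicated in* a disease.

Tables are plain TSV/CSV (UTF-8, tab preferred with comma fallback) so the
whole network is auditable line by line.  Exports go to edge-TSV, SIF and
GraphML, all of which round-trip.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import ParseError, SchemaError, UsageError, ValidationError

NODE_KINDS = ("plant", "compound", "target", "pathway", "disease")

KIND_PREFIX = {
    "plant": "ADP",
    "compound": "AC",
    "target": "PT",
    "pathway": "P",
    "disease": "D",
}
PREFIX_KIND = {v: k for k, v in KIND_PREFIX.items()}

CODE_RE = re.compile(r"^(ADP|AC|PT|P|D)([0-9]+)$")

#: edge kind -> (source node kind, target node kind)
EDGE_ENDPOINTS = {
    "contains": ("plant", "compound"),
    "targets_direct": ("compound", "target"),
    "targets_indirect": ("compound", "target"),
    "targets_nondiabetic": ("compound", "target"),
    "targets_enriched": ("compound", "target"),
    "participates_in": ("target", "pathway"),
    "implicated_in": ("target", "disease"),
}
EDGE_KINDS = tuple(EDGE_ENDPOINTS)

#: compound->target kinds counted as disease-relevant interactions
DIABETES_TARGET_KINDS = ("targets_direct", "targets_indirect")


def code_key(code: str) -> tuple[str, int]:
    """Sort key putting codes in natural order (AC2 before AC11)."""
    m = CODE_RE.match(code)
    if not m:
        raise UsageError(f"malformed node code {code!r}")
    return m.group(1), int(m.group(2))


def split_code(code: str) -> tuple[str, int]:
    """Return (prefix, index) of a code, raising ParseError if malformed."""
    m = CODE_RE.match(code)
    if m is None:
        raise ParseError(f"malformed node code {code!r}")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class NodeRecord:
    code: str
    kind: str
    name: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise ValidationError(f"unknown node kind {self.kind!r}")
        prefix, _ = split_code(self.code)
        if prefix != KIND_PREFIX[self.kind]:
            raise ValidationError(
                f"code {self.code!r} has prefix {prefix!r}, "
                f"expected {KIND_PREFIX[self.kind]!r} for kind {self.kind!r}"
            )


@dataclass(frozen=True)
class TypedEdge:
    source: str
    target: str
    kind: str
    evidence: str = ""

    def __post_init__(self):
        if self.kind not in EDGE_ENDPOINTS:
            raise SchemaError(f"unknown edge kind {self.kind!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.kind)


@dataclass
class Registry:
    """A validated collection of nodes and typed edges."""

    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    edges: list[TypedEdge] = field(default_factory=list)

    # -- construction -----------------------------------------------------
    def add_node(self, record: NodeRecord) -> None:
        if record.code in self.nodes:
            raise ValidationError(f"duplicate node code {record.code!r}")
        self.nodes[record.code] = record

    def add_edge(self, edge: TypedEdge) -> None:
        self._check_edge(edge)
        if edge.key in {e.key for e in self.edges}:
            raise ValidationError(
                f"duplicate edge ({edge.source}, {edge.target}, {edge.kind})"
            )
        self.edges.append(edge)

    def _check_edge(self, edge: TypedEdge) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                raise ValidationError(f"edge endpoint {endpoint!r} not in registry")
        src_kind, tgt_kind = EDGE_ENDPOINTS[edge.kind]
        if self.nodes[edge.source].kind != src_kind or self.nodes[edge.target].kind != tgt_kind:
            raise SchemaError(
                f"edge kind {edge.kind!r} requires {src_kind}->{tgt_kind}, got "
                f"{self.nodes[edge.source].kind}->{self.nodes[edge.target].kind} "
                f"({edge.source}->{edge.target})"
            )

    # -- queries ----------------------------------------------------------
    def node_codes(self, kind: str) -> list[str]:
        if kind not in NODE_KINDS:
            raise UsageError(f"unknown node kind {kind!r}")
        return sorted((c for c, n in self.nodes.items() if n.kind == kind), key=code_key)

    def edges_of_kind(self, *kinds: str) -> list[TypedEdge]:
        for k in kinds:
            if k not in EDGE_ENDPOINTS:
                raise UsageError(f"unknown edge kind {k!r}")
        return [e for e in self.edges if e.kind in kinds]

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {e.key for e in self.edges}

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Raise on any violated invariant; silent on a healthy registry."""
        seen_edges: set[tuple[str, str, str]] = set()
        for code, record in self.nodes.items():
            if code != record.code:
                raise ValidationError(f"node indexed as {code!r} but coded {record.code!r}")
        for edge in self.edges:
            self._check_edge(edge)
            if edge.key in seen_edges:
                raise ValidationError(f"duplicate edge {edge.key}")
            seen_edges.add(edge.key)

    def copy(self) -> "Registry":
        return Registry(nodes=dict(self.nodes), edges=list(self.edges))


# ---------------------------------------------------------------------------
# parsing


def _sniff_delimiter(header_line: str) -> str:
    # tab preferred, comma fallback
    return "\t" if "\t" in header_line else ","


def _read_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines()]
    if not lines:
        raise ParseError(f"{path}: empty file, expected a header row")
    delim = _sniff_delimiter(lines[0])
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows = list(reader)
    header = [h.strip() for h in rows[0]]
    body = [
        (i + 2, [c.strip() for c in row])
        for i, row in enumerate(rows[1:])
        if any(c.strip() for c in row)
    ]
    return header, body


def parse_node_table(path: str | Path, kind: str) -> list[NodeRecord]:
    """Read a node registry table (columns: code, name[, aliases]).

    Row order is preserved; duplicate or malformed codes raise with the
    offending code / line number.
    """
    if kind not in NODE_KINDS:
        raise UsageError(f"unknown node kind {kind!r}")
    header, body = _read_rows(path)
    lower = [h.lower() for h in header]
    if "code" not in lower or "name" not in lower:
        raise ParseError(f"{path}: header must contain 'code' and 'name', got {header}")
    icode, iname = lower.index("code"), lower.index("name")
    ialias = lower.index("aliases") if "aliases" in lower else None

    records: list[NodeRecord] = []
    seen: set[str] = set()
    for lineno, row in body:
        try:
            code = row[icode]
            name = row[iname]
        except IndexError:
            raise ParseError("too few columns", line=lineno) from None
        m = CODE_RE.match(code)
        if m is None or m.group(1) != KIND_PREFIX[kind]:
            raise ParseError(
                f"malformed {kind} code {code!r} (expected {KIND_PREFIX[kind]}<number>)",
                line=lineno,
            )
        if code in seen:
            raise ValidationError(f"duplicate code {code!r} in {path}")
        seen.add(code)
        aliases: tuple[str, ...] = ()
        if ialias is not None and len(row) > ialias and row[ialias]:
            aliases = tuple(a.strip() for a in row[ialias].split("|") if a.strip())
        records.append(NodeRecord(code=code, kind=kind, name=name, aliases=aliases))
    return records


def parse_edge_table(path: str | Path, registry: Registry) -> list[TypedEdge]:
    """Read a typed edge table (columns: source, target, kind[, evidence]).

    Every edge is validated against the registry: endpoints must resolve
    and the relation kind must agree with the endpoint node kinds.
    """
    header, body = _read_rows(path)
    lower = [h.lower() for h in header]
    required = ("source", "target", "kind")
    for col in required:
        if col not in lower:
            raise ParseError(f"{path}: header must contain {required}, got {header}")
    idx = {col: lower.index(col) for col in required}
    iev = lower.index("evidence") if "evidence" in lower else None

    edges: list[TypedEdge] = []
    seen: set[tuple[str, str, str]] = set()
    for lineno, row in body:
        try:
            source, target, kind = (row[idx[c]] for c in required)
        except IndexError:
            raise ParseError("too few columns", line=lineno) from None
        if kind not in EDGE_ENDPOINTS:
            raise ParseError(f"unknown edge kind {kind!r}", line=lineno)
        evidence = row[iev] if iev is not None and len(row) > iev else ""
        edge = TypedEdge(source=source, target=target, kind=kind, evidence=evidence)
        for endpoint in (source, target):
            if endpoint not in registry.nodes:
                raise ValidationError(
                    f"{path} line {lineno}: unknown code {endpoint!r}"
                )
        registry._check_edge(edge)  # schema (endpoint-kind) check
        if edge.key in seen:
            raise ValidationError(f"{path} line {lineno}: duplicate edge {edge.key}")
        seen.add(edge.key)
        edges.append(edge)
    return edges


def group_edges_by_kind(edges: list[TypedEdge]) -> dict[str, list[TypedEdge]]:
    grouped: dict[str, list[TypedEdge]] = {}
    for e in edges:
        grouped.setdefault(e.kind, []).append(e)
    return grouped


# ---------------------------------------------------------------------------
# export / import

EXPORT_FORMATS = ("edge-tsv", "sif", "graphml")


def export_network(registry: Registry, fmt: str, path: str | Path) -> Path:
    """Write the registry's edge set in an interchange format.

    ``edge-tsv`` and ``graphml`` are round-trip safe; ``sif`` uses the
    relation kind as the interaction label (one edge per line).
    """
    path = Path(path)
    edges = sorted(registry.edges, key=lambda e: (code_key(e.source), code_key(e.target), e.kind))
    if fmt == "edge-tsv":
        lines = ["source\ttarget\tkind\tevidence"]
        lines += [f"{e.source}\t{e.target}\t{e.kind}\t{e.evidence}" for e in edges]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "sif":
        lines = [f"{e.source}\t{e.kind}\t{e.target}" for e in edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif fmt == "graphml":
        g = to_networkx(registry)
        nx.write_graphml(g, path)
    else:
        raise UsageError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    return path


def to_networkx(registry: Registry) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for code in sorted(registry.nodes, key=code_key):
        node = registry.nodes[code]
        g.add_node(code, kind=node.kind, name=node.name, aliases="|".join(node.aliases))
    for e in registry.edges:
        g.add_edge(e.source, e.target, kind=e.kind, evidence=e.evidence)
    return g


def from_networkx(g: nx.MultiDiGraph) -> Registry:
    reg = Registry()
    for code, data in g.nodes(data=True):
        aliases = tuple(a for a in str(data.get("aliases", "")).split("|") if a)
        reg.add_node(
            NodeRecord(code=code, kind=data["kind"], name=data.get("name", ""), aliases=aliases)
        )
    for src, tgt, data in g.edges(data=True):
        reg.add_edge(
            TypedEdge(source=src, target=tgt, kind=data["kind"], evidence=data.get("evidence", ""))
        )
    reg.validate()
    return reg


def import_graphml(path: str | Path) -> Registry:
    return from_networkx(nx.read_graphml(path, force_multigraph=True))


def import_edge_tsv(path: str | Path, registry_nodes: Registry) -> list[TypedEdge]:
    """Re-import an exported edge-TSV against an existing node registry."""
    return parse_edge_table(path, registry_nodes)
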