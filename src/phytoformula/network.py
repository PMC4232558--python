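"""Layered network views and degree/hub/coverage statistics.

A :class:`LayeredNetwork` is a read-only view over a validated
:class:`~phytoformula.registry.Registry`, organised into the four bipartite
layers of the study design: plant-compound (``ADP-AC``), compound-target
(``AC-PT``), target-pathway (``PT-P``) and target-disease (``PT-D``).

Degree is the central statistic: the number of neighbours a node has in a
layer, counting only the requested edge kinds.  Compound-side degree in the
AC-PT layer (direct + indirect disease-target edges, non-disease edges
excluded) is what the formulation selector thresholds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UsageError
from .registry import (
    DIABETES_TARGET_KINDS,
    Registry,
    TypedEdge,
    code_key,
)

#: layer name -> (left node kind, right node kind, edge kinds)
LAYERS = {
    "ADP-AC": ("plant", "compound", ("contains",)),
    "AC-PT": (
        "compound",
        "target",
        ("targets_direct", "targets_indirect", "targets_nondiabetic", "targets_enriched"),
    ),
    "PT-P": ("target", "pathway", ("participates_in",)),
    "PT-D": ("target", "disease", ("implicated_in",)),
}

SIDES = ("left", "right")


@dataclass
class DegreeReport:
    """Per-node degrees on one side of a bipartite layer."""

    layer: str
    side: str
    kinds: tuple[str, ...]
    degrees: dict[str, int] = field(default_factory=dict)

    @property
    def min_degree(self) -> int:
        return min(self.degrees.values()) if self.degrees else 0

    @property
    def max_degree(self) -> int:
        return max(self.degrees.values()) if self.degrees else 0


class LayeredNetwork:
    """Bipartite layers over a registry, with per-layer edge lists."""

    def __init__(self, registry: Registry):
        registry.validate()
        self.registry = registry
        self._layer_edges: dict[str, list[TypedEdge]] = {
            name: [e for e in registry.edges if e.kind in kinds]
            for name, (_, _, kinds) in LAYERS.items()
        }

    @classmethod
    def from_registry(cls, registry: Registry) -> "LayeredNetwork":
        return cls(registry)

    # -- layer access -----------------------------------------------------
    def layer_edges(self, layer: str, kinds: tuple[str, ...] | None = None) -> list[TypedEdge]:
        if layer not in LAYERS:
            raise UsageError(f"unknown layer {layer!r}; choose from {tuple(LAYERS)}")
        edges = self._layer_edges[layer]
        if kinds is None:
            return list(edges)
        allowed = LAYERS[layer][2]
        for k in kinds:
            if k not in allowed:
                raise UsageError(f"edge kind {k!r} does not belong to layer {layer!r}")
        return [e for e in edges if e.kind in kinds]

    def layer_nodes(self, layer: str, side: str) -> list[str]:
        """Nodes on one side of a layer: endpoints of any edge of the layer."""
        if side not in SIDES:
            raise UsageError(f"unknown side {side!r}; choose 'left' or 'right'")
        edges = self.layer_edges(layer)
        codes = {e.source for e in edges} if side == "left" else {e.target for e in edges}
        return sorted(codes, key=code_key)

    # -- statistics -------------------------------------------------------
    def degree(
        self,
        layer: str,
        side: str,
        kinds: tuple[str, ...] | None = None,
    ) -> DegreeReport:
        """Degree of every node on ``side`` of ``layer``.

        Layer membership counts edges of any kind belonging to the layer;
        the degree itself counts only ``kinds`` (default: all layer kinds).
        """
        if kinds is not None and not kinds:
            raise UsageError("kinds must be non-empty (pass None for all layer kinds)")
        members = self.layer_nodes(layer, side)
        counted = self.layer_edges(layer, kinds)
        degrees = {code: 0 for code in members}
        for e in counted:
            endpoint = e.source if side == "left" else e.target
            degrees[endpoint] += 1
        used = tuple(kinds) if kinds is not None else LAYERS[layer][2]
        return DegreeReport(layer=layer, side=side, kinds=used, degrees=degrees)

    def compound_target_degree(
        self, kinds: tuple[str, ...] = DIABETES_TARGET_KINDS
    ) -> DegreeReport:
        """Compound-side AC-PT degree over disease-relevant edge kinds."""
        return self.degree("AC-PT", "left", kinds)

    def coverage_fraction(self, plant_subset: set[str] | list[str]) -> float:
        """Fraction of all compound nodes adjacent to the given plants."""
        subset = set(plant_subset)
        if not subset:
            raise UsageError("plant subset must be non-empty")
        plants = set(self.registry.node_codes("plant"))
        unknown = subset - plants
        if unknown:
            raise UsageError(f"unknown plant codes: {sorted(unknown)}")
        compounds = self.registry.node_codes("compound")
        if not compounds:
            raise UsageError("network has no compound nodes; coverage undefined")
        covered = {
            e.target for e in self.layer_edges("ADP-AC") if e.source in subset
        }
        return len(covered & set(compounds)) / len(compounds)

    def direct_targets(self, compound: str) -> set[str]:
        """The protein targets a compound binds (direct edges only)."""
        if compound not in self.registry.nodes:
            raise UsageError(f"unknown compound code {compound!r}")
        return {
            e.target
            for e in self.layer_edges("AC-PT", ("targets_direct",))
            if e.source == compound
        }

    def targets_of(self, compound: str, kinds: tuple[str, ...] = DIABETES_TARGET_KINDS) -> set[str]:
        if compound not in self.registry.nodes:
            raise UsageError(f"unknown compound code {compound!r}")
        return {e.target for e in self.layer_edges("AC-PT", kinds) if e.source == compound}

    def binders_of(self, target: str, kinds: tuple[str, ...] = DIABETES_TARGET_KINDS) -> set[str]:
        """Compounds with an edge of the given kinds onto a protein target."""
        if target not in self.registry.nodes:
            raise UsageError(f"unknown target code {target!r}")
        return {e.source for e in self.layer_edges("AC-PT", kinds) if e.target == target}

    def shared_target_partners(self, compound: str) -> dict[str, set[str]]:
        """Map of partner compound -> direct targets shared with ``compound``.

        Only binding (direct) interactions count; the compound itself is
        excluded.  Symmetric by construction.
        """
        own = self.direct_targets(compound)
        partners: dict[str, set[str]] = {}
        if not own:
            return partners
        for e in self.layer_edges("AC-PT", ("targets_direct",)):
            if e.source != compound and e.target in own:
                partners.setdefault(e.source, set()).add(e.target)
        return partners


def hubs(report: DegreeReport, threshold: int) -> list[str]:
    """Nodes with degree >= threshold, sorted by (degree desc, code asc)."""
    if threshold < 0:
        raise UsageError("threshold must be non-negative")
    selected = [(code, d) for code, d in report.degrees.items() if d >= threshold]
    selected.sort(key=lambda item: (-item[1], code_key(item[0])))
    return [code for code, _ in selected]


def brute_force_degree(
    edges: list[TypedEdge], side: str, kinds: tuple[str, ...]
) -> dict[str, int]:
    """Independent degree count straight off an edge list (test oracle)."""
    degrees: dict[str, int] = {}
    for e in edges:
        endpoint = e.source if side == "left" else e.target
        degrees.setdefault(endpoint, 0)
        if e.kind in kinds:
            degrees[endpoint] += 1
    return degrees
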