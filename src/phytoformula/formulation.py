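"""Threshold-degree formulation selection.

The selection algebra works on two bipartite layers.  Writing ``x_i`` for
the disease-target degree of compound *i* in the compound-target layer and
``y_j`` for the pathway degree of protein *j* in the target-pathway layer:

* ``AC_PT``  - compounds with ``x_i >=`` the compound threshold (default 4),
  i.e. the multi-target compounds;
* ``PT_P``   - proteins with ``y_j >=`` the pathway threshold (default 4),
  i.e. the multi-pathway proteins;
* ``AC{PT_P(j)}`` - for each multi-pathway protein *j*, the highest-degree
  compound among those that target it (ties broken by lowest code);
* the ideal formulation ``IF = AC_PT ∪ {AC{PT_P(j)} : j in PT_P}``.

``PT_P`` may alternatively be supplied as an explicit override set, for use
when the multi-pathway proteins are asserted by curation rather than
derivable from a complete target-pathway edge list.

Every selection keeps a full trace (per-compound degrees, per-target
binder candidates and ties) so the result is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError, UsageError
from .network import LayeredNetwork, hubs
from .registry import DIABETES_TARGET_KINDS, code_key


@dataclass
class FormulationConfig:
    compound_threshold: int = 4
    pathway_threshold: int = 4
    degree_kinds: tuple[str, ...] = DIABETES_TARGET_KINDS
    pt_p_override: frozenset[str] | None = None
    tie_break: str = "code_asc"

    def __post_init__(self):
        if self.compound_threshold < 1 or self.pathway_threshold < 1:
            raise ConfigError("thresholds must be >= 1")
        if self.tie_break != "code_asc":
            raise ConfigError(f"unknown tie_break {self.tie_break!r}")
        if self.pt_p_override is not None:
            self.pt_p_override = frozenset(self.pt_p_override)


@dataclass
class FormulationResult:
    ac_pt: set[str]
    pt_p: set[str]
    ac_ptp: dict[str, str]
    ideal_formulation: set[str]
    compound_degrees: dict[str, int] = field(default_factory=dict)
    binder_trace: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    unbound_targets: set[str] = field(default_factory=set)
    config: FormulationConfig | None = None

    def to_dict(self) -> dict:
        return {
            "ac_pt": sorted(self.ac_pt, key=code_key),
            "pt_p": sorted(self.pt_p, key=code_key),
            "ac_ptp": {t: self.ac_ptp[t] for t in sorted(self.ac_ptp, key=code_key)},
            "ideal_formulation": sorted(self.ideal_formulation, key=code_key),
            "compound_degrees": {
                c: self.compound_degrees[c] for c in sorted(self.compound_degrees, key=code_key)
            },
            "binder_trace": {
                t: self.binder_trace[t] for t in sorted(self.binder_trace, key=code_key)
            },
            "unbound_targets": sorted(self.unbound_targets, key=code_key),
        }


def select_ac_pt(network: LayeredNetwork, config: FormulationConfig) -> set[str]:
    """Compounds whose disease-target degree meets the compound threshold."""
    report = network.degree("AC-PT", "left", config.degree_kinds)
    return set(hubs(report, config.compound_threshold))


def select_pt_p(network: LayeredNetwork, config: FormulationConfig) -> set[str]:
    """Multi-pathway protein targets (or the explicit override set)."""
    if config.pt_p_override is not None:
        known = set(network.registry.node_codes("target"))
        unknown = set(config.pt_p_override) - known
        if unknown:
            raise UsageError(f"pt_p_override contains unknown target codes: {sorted(unknown)}")
        return set(config.pt_p_override)
    report = network.degree("PT-P", "left")
    return set(hubs(report, config.pathway_threshold))


def select_ac_ptp(
    network: LayeredNetwork,
    pt_p: set[str],
    config: FormulationConfig,
) -> tuple[dict[str, str], dict[str, list[tuple[str, int]]], set[str]]:
    """Best binder per multi-pathway target.

    Returns (target -> chosen compound, target -> ranked candidate trace,
    targets with no binder).  The chosen compound is the binder with
    maximal disease-target degree; ties go to the lowest compound code and
    all tied candidates stay visible in the trace.
    """
    degrees = network.degree("AC-PT", "left", config.degree_kinds).degrees
    chosen: dict[str, str] = {}
    trace: dict[str, list[tuple[str, int]]] = {}
    unbound: set[str] = set()
    for target in sorted(pt_p, key=code_key):
        binders = network.binders_of(target, config.degree_kinds)
        ranked = sorted(
            ((c, degrees.get(c, 0)) for c in binders),
            key=lambda item: (-item[1], code_key(item[0])),
        )
        trace[target] = ranked
        if ranked:
            chosen[target] = ranked[0][0]
        else:
            unbound.add(target)
    return chosen, trace, unbound


def ideal_formulation(
    network: LayeredNetwork, config: FormulationConfig | None = None
) -> FormulationResult:
    """Full selection: IF = AC_PT ∪ values(AC{PT_P(j)})."""
    config = config or FormulationConfig()
    ac_pt = select_ac_pt(network, config)
    pt_p = select_pt_p(network, config)
    ac_ptp, trace, unbound = select_ac_ptp(network, pt_p, config)
    result = FormulationResult(
        ac_pt=ac_pt,
        pt_p=pt_p,
        ac_ptp=ac_ptp,
        ideal_formulation=ac_pt | set(ac_ptp.values()),
        compound_degrees=network.degree("AC-PT", "left", config.degree_kinds).degrees,
        binder_trace=trace,
        unbound_targets=unbound,
        config=config,
    )
    return result
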