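"""Pharmacophore-gated target enrichment.

For a multi-target seed compound, enrichment proposes new protein targets
propagated from *partner* compounds: compounds that share at least one
directly-bound target with the seed.  A partner's remaining direct targets
are proposed for the seed only if the two compounds pass the pharmacophore
feature-similarity gate; partners failing the gate are recorded as
rejected, and seeds without any partner are recorded as such — every
outcome carries full provenance.

The original study verified each proposal by protein-ligand docking; here
the gate is the similarity verdict plus an optional caller-supplied
proposal filter through which an external docking score (or any veto
logic) can be plugged in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

from .errors import EnrichmentError
from .network import LayeredNetwork
from .pharmacophore import PharmacophoreProfile, SimilarityScore, similarity
from .registry import Registry, TypedEdge, code_key

log = logging.getLogger(__name__)

STATUS_PROPOSED = "proposed"
STATUS_REJECTED = "rejected_dissimilar"
STATUS_NO_PARTNER = "no_partner"


@dataclass
class EnrichmentConfig:
    similarity_threshold: float
    #: optional veto hook: called with each would-be proposal; return False to drop it
    proposal_filter: Callable[["EnrichmentProposal"], bool] | None = None
    #: optional mode: cap the number of propagated targets in proportion to
    #: the similarity score (higher similarity, more shared targets); off by
    #: default since no quantitative propagation rule is established
    proportional_cap: bool = False


@dataclass
class EnrichmentProposal:
    seed: str
    partner: str | None
    shared_targets: set[str] = field(default_factory=set)
    proposed_targets: set[str] = field(default_factory=set)
    similarity: SimilarityScore | None = None
    status: str = STATUS_PROPOSED

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "partner": self.partner,
            "shared_targets": sorted(self.shared_targets, key=code_key),
            "proposed_targets": sorted(self.proposed_targets, key=code_key),
            "similarity": None if self.similarity is None else round(self.similarity.score, 4),
            "status": self.status,
        }


def find_seeds(
    network: LayeredNetwork,
    min_direct_degree: int | None = None,
    top_k: int | None = None,
) -> list[str]:
    """Compounds ranked by direct-target count, filtered by the criterion."""
    report = network.degree("AC-PT", "left", ("targets_direct",))
    ranked = sorted(report.degrees.items(), key=lambda item: (-item[1], code_key(item[0])))
    if min_direct_degree is not None:
        ranked = [(c, d) for c, d in ranked if d >= min_direct_degree]
    if top_k is not None:
        ranked = ranked[:top_k]
    return [c for c, _ in ranked]


def enrich(
    network: LayeredNetwork,
    profiles: dict[str, PharmacophoreProfile],
    seed: str,
    config: EnrichmentConfig,
) -> list[EnrichmentProposal]:
    """Enrichment proposals for one seed compound."""
    seed_targets = network.direct_targets(seed)
    if not seed_targets:
        raise EnrichmentError(f"seed {seed} has no direct protein targets")
    if seed not in profiles:
        raise EnrichmentError(f"no structure/profile available for seed {seed}")

    partners = network.shared_target_partners(seed)
    if not partners:
        return [EnrichmentProposal(seed=seed, partner=None, status=STATUS_NO_PARTNER)]

    proposals: list[EnrichmentProposal] = []
    for partner in sorted(partners, key=code_key):
        if partner not in profiles:
            log.warning("partner %s of seed %s has no structure; skipped", partner, seed)
            continue
        sim = similarity(
            profiles[seed], profiles[partner], threshold=config.similarity_threshold
        )
        shared = partners[partner]
        if sim.verdict == "similar":
            proposed = network.direct_targets(partner) - seed_targets
            if config.proportional_cap and proposed:
                cap = max(1, int(round(sim.score * len(proposed))))
                proposed = set(sorted(proposed, key=code_key)[:cap])
            prop = EnrichmentProposal(
                seed=seed,
                partner=partner,
                shared_targets=shared,
                proposed_targets=proposed,
                similarity=sim,
                status=STATUS_PROPOSED,
            )
            if config.proposal_filter is not None and not config.proposal_filter(prop):
                prop.status = STATUS_REJECTED
                prop.proposed_targets = set()
        else:
            prop = EnrichmentProposal(
                seed=seed,
                partner=partner,
                shared_targets=shared,
                proposed_targets=set(),
                similarity=sim,
                status=STATUS_REJECTED,
            )
        proposals.append(prop)
    return proposals


def proposed_targets_for(proposals: list[EnrichmentProposal]) -> set[str]:
    """Union of proposed targets across a seed's proposal records."""
    out: set[str] = set()
    for p in proposals:
        if p.status == STATUS_PROPOSED:
            out |= p.proposed_targets
    return out


def enrich_all(
    network: LayeredNetwork,
    profiles: dict[str, PharmacophoreProfile],
    config: EnrichmentConfig,
    seeds: list[str] | None = None,
    min_direct_degree: int = 4,
) -> tuple[Registry, list[EnrichmentProposal]]:
    """Run enrichment for every seed; return an enriched copy plus the log.

    Proposed interactions are added to a *copy* of the registry under the
    distinct ``targets_enriched`` kind; the input network is untouched.
    Edges that already exist under any compound-target kind are never
    duplicated, so the operation is idempotent.
    """
    if seeds is None:
        seeds = find_seeds(network, min_direct_degree=min_direct_degree)
    enriched = network.registry.copy()
    existing = {
        (e.source, e.target)
        for e in enriched.edges
        if e.kind.startswith("targets_")
    }
    all_proposals: list[EnrichmentProposal] = []
    for seed in seeds:
        proposals = enrich(network, profiles, seed, config)
        all_proposals.extend(proposals)
        for target in sorted(proposed_targets_for(proposals), key=code_key):
            if (seed, target) in existing:
                continue
            enriched.add_edge(
                TypedEdge(
                    source=seed,
                    target=target,
                    kind="targets_enriched",
                    evidence=f"enrichment:{seed}",
                )
            )
            existing.add((seed, target))
    enriched.validate()
    return enriched, all_proposals
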