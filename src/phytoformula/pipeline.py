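"""End-to-end pipeline: validate -> build -> formulate -> profile -> enrich -> adme.

Each stage writes a machine-readable artifact (JSON or TSV) into the run
directory; a ``summary.json`` collects the headline results.  Stage
failures surface as exceptions with the stage name; partial outputs are
left in place for inspection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import admet, enrichment, formulation, pharmacophore
from .errors import PhytoformulaError, UsageError
from .fixture import load_fixture
from .network import LayeredNetwork, LAYERS
from .registry import code_key, export_network

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    data_dir: str | None = None  # None -> packaged curated fixture
    out_dir: str = "phytoformula_run"
    compound_threshold: int = 4
    pathway_threshold: int = 4
    min_direct_degree: int = 4
    similarity_threshold: float | None = None  # None -> packaged calibrated value
    pt_p_override: tuple[str, ...] | None = None
    adme_windows: dict[str, tuple[float, float]] = field(default_factory=dict)
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        if "pt_p_override" in raw and raw["pt_p_override"] is not None:
            raw["pt_p_override"] = tuple(raw["pt_p_override"])
        return cls(**raw)

    def resolved(self) -> "PipelineConfig":
        defaults = pharmacophore.load_default_config()
        if self.similarity_threshold is None:
            self.similarity_threshold = float(defaults["similarity_threshold"])
        if not self.adme_windows:
            self.adme_windows = {
                k: tuple(v) for k, v in defaults.get("adme_windows", {}).items()
            }
        if self.pt_p_override is None and defaults.get("pt_p_override"):
            self.pt_p_override = tuple(defaults["pt_p_override"])
        return self


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return (and write) the summary report."""
    config = config.resolved()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}

    stage = "validate"
    try:
        registry, structures = load_fixture(config.data_dir)
        registry.validate()
        summary["stages"].append(stage)
        summary["nodes"] = {
            kind: len(registry.node_codes(kind))
            for kind in ("plant", "compound", "target", "pathway", "disease")
        }
        summary["edges"] = len(registry.edges)

        stage = "build"
        network = LayeredNetwork(registry)
        layer_stats = {}
        for layer in LAYERS:
            report = network.degree(layer, "left")
            layer_stats[layer] = {
                "edges": len(network.layer_edges(layer)),
                "min_degree": report.min_degree,
                "max_degree": report.max_degree,
            }
        _write_json(out / "network_stats.json", layer_stats)
        export_network(registry, "edge-tsv", out / "edges.tsv")
        summary["stages"].append(stage)

        stage = "formulate"
        fconfig = formulation.FormulationConfig(
            compound_threshold=config.compound_threshold,
            pathway_threshold=config.pathway_threshold,
            pt_p_override=(
                frozenset(config.pt_p_override) if config.pt_p_override else None
            ),
        )
        result = formulation.ideal_formulation(network, fconfig)
        _write_json(out / "formulation.json", result.to_dict())
        summary["ideal_formulation"] = sorted(result.ideal_formulation, key=code_key)
        summary["stages"].append(stage)

        stage = "profile"
        profiles = pharmacophore.profile_table(structures)
        _write_json(
            out / "profiles.json",
            {c: p.feature_counts for c, p in sorted(profiles.items())},
        )
        summary["profiled_compounds"] = len(profiles)
        summary["stages"].append(stage)

        stage = "enrich"
        econfig = enrichment.EnrichmentConfig(
            similarity_threshold=config.similarity_threshold
        )
        enriched, proposals = enrichment.enrich_all(
            network, profiles, econfig, min_direct_degree=config.min_direct_degree
        )
        _write_json(out / "enrichment.json", [p.to_dict() for p in proposals])
        export_network(enriched, "edge-tsv", out / "edges_enriched.tsv")
        summary["enriched_edges"] = sum(
            1 for e in enriched.edges if e.kind == "targets_enriched"
        )
        summary["stages"].append(stage)

        stage = "adme"
        records = admet.screen_table(structures, windows=config.adme_windows)
        lines = ["code\tmw\tdonors\tacceptors\tlogp\tviolations\twindow_flags"]
        for r in sorted(records, key=lambda r: code_key(r.code)):
            flags = ";".join(f"{k}={v}" for k, v in sorted(r.window_flags.items()))
            lines.append(
                f"{r.code}\t{r.mw:.2f}\t{r.donors}\t{r.acceptors}\t"
                f"{r.logp:.3f}\t{r.violations}\t{flags}"
            )
        (out / "adme.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        summary["max_violations"] = max(r.violations for r in records)
        summary["max_mw"] = round(max(r.mw for r in records), 2)
        summary["stages"].append(stage)
    except PhytoformulaError as exc:
        log.error("stage %s failed: %s", stage, exc)
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        _write_json(out / "summary.json", summary)
        raise

    _write_json(out / "summary.json", summary)
    return summary
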