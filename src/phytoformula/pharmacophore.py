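"""Pharmacophore feature typing and feature-count similarity.

Each compound structure is typed into six classical pharmacophore feature
classes — H-bond acceptor (A), H-bond donor (D), hydrophobic (H),
negatively ionizable (N), positively ionizable (P) and aromatic ring (R) —
using a packaged, versioned SMARTS rule table.  The profile is the integer
count vector over those classes.

Similarity between two compounds is the Tanimoto coefficient on the count
vectors, ``sum_c min(a_c, b_c) / sum_c max(a_c, b_c)``, which is symmetric,
lies in [0, 1] and equals 1 for identical non-empty profiles.  This is an
alignment-free stand-in for 3D feature alignment: the package asserts and
relies on the *ordering* it induces between feature-similar and
feature-dissimilar compound pairs, not on absolute score values.  The
similar/dissimilar verdict threshold is calibrated as the midpoint between
the lowest similar-pair score and the highest dissimilar-pair score on the
curated labeled pairs, and is stored in configuration, never hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit import RDLogger

from .errors import StructureError, UndefinedSimilarityError

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # RDKit parse chatter; errors are raised instead

FEATURE_CLASSES = ("A", "D", "H", "N", "P", "R")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("phytoformula") / "data" / name))


def load_rules(path: str | Path | None = None) -> dict:
    """Load the versioned feature rule table (packaged default)."""
    path = Path(path) if path else _data_path("pharmacophore_rules.yaml")
    rules = yaml.safe_load(path.read_text(encoding="utf-8"))
    missing = set(FEATURE_CLASSES) - set(rules.get("features", {}))
    if missing:
        raise ValueError(f"rule table {path} lacks feature classes {sorted(missing)}")
    return rules


def load_default_config() -> dict:
    """Packaged defaults (similarity threshold, selection thresholds)."""
    return yaml.safe_load(_data_path("default_config.yaml").read_text(encoding="utf-8"))


@dataclass(frozen=True)
class PharmacophoreProfile:
    code: str
    smiles: str
    feature_counts: dict[str, int]

    def vector(self) -> tuple[int, ...]:
        return tuple(self.feature_counts[c] for c in FEATURE_CLASSES)

    def is_empty(self) -> bool:
        return sum(self.feature_counts.values()) == 0


@dataclass(frozen=True)
class SimilarityScore:
    pair: tuple[str, str]
    score: float
    metric: str
    threshold: float
    verdict: str  # "similar" | "dissimilar"


def _mol_from_smiles(smiles: str, code: str | None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" for compound {code}" if code else ""
        raise StructureError(f"unparsable SMILES{label}: {smiles!r}")
    return mol


def _count_atoms(mol: Chem.Mol, smarts_list: list[str]) -> int:
    atoms: set[int] = set()
    for smarts in smarts_list:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in rule table: {smarts!r}")
        for match in mol.GetSubstructMatches(patt):
            atoms.update(match)
    return len(atoms)


def _count_matches(mol: Chem.Mol, smarts_list: list[str]) -> int:
    n = 0
    for smarts in smarts_list:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in rule table: {smarts!r}")
        n += len(mol.GetSubstructMatches(patt))
    return n


def _count_aromatic_rings(mol: Chem.Mol) -> int:
    ri = mol.GetRingInfo()
    count = 0
    for ring in ri.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            count += 1
    return count


def profile(
    smiles: str, rules: dict | None = None, code: str | None = None
) -> PharmacophoreProfile:
    """Type a structure into the six feature classes.

    Counting modes per class come from the rule table: ``atoms`` (number of
    distinct atoms matched by any pattern), ``matches`` (number of
    substructure group matches) or ``rings`` (aromatic ring count).
    """
    rules = rules or load_rules()
    mol = _mol_from_smiles(smiles, code)
    counts: dict[str, int] = {}
    for cls in FEATURE_CLASSES:
        spec = rules["features"][cls]
        mode = spec.get("mode", "atoms")
        if mode == "rings":
            counts[cls] = _count_aromatic_rings(mol)
        elif mode == "matches":
            counts[cls] = _count_matches(mol, spec.get("smarts", []))
        elif mode == "atoms":
            counts[cls] = _count_atoms(mol, spec.get("smarts", []))
        else:
            raise ValueError(f"unknown counting mode {mode!r} for class {cls}")
    return PharmacophoreProfile(code=code or "", smiles=smiles, feature_counts=counts)


def profile_table(
    structures: "list[tuple[str, str]] | dict[str, str]",
    rules: dict | None = None,
) -> dict[str, PharmacophoreProfile]:
    """Profile many (code, SMILES) entries, skipping unparsable ones loudly."""
    rules = rules or load_rules()
    items = structures.items() if isinstance(structures, dict) else structures
    profiles: dict[str, PharmacophoreProfile] = {}
    for code, smiles in items:
        try:
            profiles[code] = profile(smiles, rules, code=code)
        except StructureError as exc:
            log.warning("skipping %s: %s", code, exc)
    return profiles


def similarity(
    a: PharmacophoreProfile,
    b: PharmacophoreProfile,
    threshold: float | None = None,
) -> SimilarityScore:
    """Count-vector Tanimoto similarity with a similar/dissimilar verdict."""
    if a.is_empty() and b.is_empty():
        raise UndefinedSimilarityError(
            f"similarity undefined between all-zero profiles {a.code!r} and {b.code!r}"
        )
    if threshold is None:
        threshold = float(load_default_config()["similarity_threshold"])
    num = sum(min(x, y) for x, y in zip(a.vector(), b.vector()))
    den = sum(max(x, y) for x, y in zip(a.vector(), b.vector()))
    score = num / den
    return SimilarityScore(
        pair=(a.code, b.code),
        score=score,
        metric="count_tanimoto",
        threshold=threshold,
        verdict="similar" if score >= threshold else "dissimilar",
    )


def load_calibration_pairs(path: str | Path | None = None) -> dict[str, list[tuple[str, str]]]:
    """Curated labeled pairs used to place the verdict threshold."""
    path = Path(path) if path else _data_path("calibration_pairs.yaml")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    groups: dict[str, list[str]] = {
        k: v for k, v in raw.items() if k not in ("similar", "dissimilar") and isinstance(v, list)
    }
    out: dict[str, list[tuple[str, str]]] = {"similar": [], "dissimilar": []}
    for label in out:
        for entry in raw.get(label, []):
            if "pair" in entry:
                out[label].append((entry["pair"][0], entry["pair"][1]))
            elif "group" in entry:
                members = groups[entry["group"].replace("-", "_")]
                for i, a in enumerate(members):
                    for b in members[i + 1 :]:
                        out[label].append((a, b))
    return out


def calibrate_threshold(
    profiles: dict[str, PharmacophoreProfile],
    similar_pairs: list[tuple[str, str]],
    dissimilar_pairs: list[tuple[str, str]],
) -> float:
    """Midpoint between the lowest similar and highest dissimilar score.

    Raises ValueError if the labels are not separable (overlapping score
    ranges), since a verdict threshold would then be meaningless.
    """

    def score(p: tuple[str, str]) -> float:
        return similarity(profiles[p[0]], profiles[p[1]], threshold=0.0).score

    lo_sim = min(score(p) for p in similar_pairs)
    hi_dis = max(score(p) for p in dissimilar_pairs)
    if lo_sim <= hi_dis:
        raise ValueError(
            f"labeled pairs not separable: min similar {lo_sim:.3f} <= "
            f"max dissimilar {hi_dis:.3f}"
        )
    return (lo_sim + hi_dis) / 2.0
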