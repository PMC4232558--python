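"""Drug-likeness descriptors and acceptance-window screening.

Computes the four properties behind Lipinski's rule of five — molecular
weight, H-bond donor count, H-bond acceptor count and an atom-contribution
logP estimate (Wildman-Crippen) — and counts rule violations
(MW > 500, logP > 5, donors > 5, acceptors > 10; each contributes one).

Donor and acceptor counts use the same packaged rule table as the
pharmacophore profiler, so the two screens agree on what a donor is.

Proprietary permeability/solubility descriptors (Caco-2, MDCK, logS,
% oral absorption) are not computed here; the window screen accepts them
as externally supplied values and otherwise marks those properties
not-evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .errors import ConfigError, StructureError
from .pharmacophore import load_rules, profile


@dataclass
class DescriptorRecord:
    code: str
    smiles: str
    mw: float
    donors: int
    acceptors: int
    logp: float
    violations: int = 0
    window_flags: dict[str, str] = field(default_factory=dict)


def descriptors(
    smiles: str, code: str | None = None, rules: dict | None = None
) -> DescriptorRecord:
    """Compute MW, donors, acceptors, logP and the rule-of-five count."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" for compound {code}" if code else ""
        raise StructureError(f"unparsable SMILES{label}: {smiles!r}")
    rules = rules or load_rules()
    prof = profile(smiles, rules, code=code)
    record = DescriptorRecord(
        code=code or "",
        smiles=smiles,
        mw=Descriptors.MolWt(mol),
        donors=prof.feature_counts["D"],
        acceptors=prof.feature_counts["A"],
        logp=Crippen.MolLogP(mol),
    )
    record.violations = lipinski_violations(record)
    return record


def lipinski_violations(record: DescriptorRecord) -> int:
    """Rule-of-five violation count in 0..4."""
    return sum(
        [
            record.mw > 500.0,
            record.logp > 5.0,
            record.donors > 5,
            record.acceptors > 10,
        ]
    )


#: property name -> attribute of DescriptorRecord this screen can compute
_COMPUTED = {"mw": "mw", "logp": "logp", "donors": "donors", "acceptors": "acceptors"}


def window_screen(
    record: DescriptorRecord,
    windows: dict[str, tuple[float, float]],
    external: dict[str, float] | None = None,
) -> dict[str, str]:
    """Flag each property as in/out of its [lo, hi] acceptance window.

    Properties this screen cannot compute take externally supplied values
    (``external``) or are flagged ``not_evaluated``.  Also stores the flags
    on the record and returns them.
    """
    external = external or {}
    flags: dict[str, str] = {}
    for prop, window in windows.items():
        try:
            lo, hi = float(window[0]), float(window[1])
        except (TypeError, ValueError, IndexError):
            raise ConfigError(f"window for {prop!r} must be a [lo, hi] pair") from None
        if lo > hi:
            raise ConfigError(f"window for {prop!r} has lo {lo} > hi {hi}")
        if prop in _COMPUTED:
            value = getattr(record, _COMPUTED[prop])
        elif prop in external:
            value = external[prop]
        else:
            flags[prop] = "not_evaluated"
            continue
        flags[prop] = "in" if lo <= value <= hi else "out"
    record.window_flags = flags
    return flags


def screen_table(
    structures: "list[tuple[str, str]] | dict[str, str]",
    windows: dict[str, tuple[float, float]] | None = None,
    external: dict[str, dict[str, float]] | None = None,
    rules: dict | None = None,
) -> list[DescriptorRecord]:
    """Descriptor + window screen over a (code, SMILES) table."""
    rules = rules or load_rules()
    items = structures.items() if isinstance(structures, dict) else structures
    records = []
    for code, smiles in items:
        rec = descriptors(smiles, code=code, rules=rules)
        if windows:
            window_screen(rec, windows, (external or {}).get(code))
        records.append(rec)
    return records
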