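"""Exception hierarchy.

Every category of invalid input maps to exactly one exception class so
callers (and tests) can distinguish parse problems from referential or
schema violations.
"""


class PhytoformulaError(Exception):
    """Base class for all package errors."""


class ParseError(PhytoformulaError):
    """A table row could not be parsed (malformed code, bad column count)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PhytoformulaError):
    """A registry invariant is violated (duplicate code, dangling edge)."""


class SchemaError(PhytoformulaError):
    """An edge kind is incompatible with its endpoint node kinds."""


class UsageError(PhytoformulaError):
    """A caller asked for something that does not exist (layer, side, code)."""


class ConfigError(PhytoformulaError):
    """An infeasible or contradictory configuration."""


class StructureError(PhytoformulaError):
    """A SMILES string could not be parsed."""


class UndefinedSimilarityError(PhytoformulaError):
    """Similarity between two all-zero pharmacophore profiles."""


class EnrichmentError(PhytoformulaError):
    """Target enrichment cannot run (e.g. the seed has no structure)."""
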