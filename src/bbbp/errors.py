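"""Exception types shared across the package."""


class BBBPError(Exception):
    """Base class for all package-specific errors."""


class InvalidSmilesError(BBBPError, ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"invalid SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class SchemaError(BBBPError, ValueError):
    """An input table is missing a required column or has a malformed row."""


class ConfigurationError(BBBPError, ValueError):
    """A rule table or descriptor set is misconfigured (e.g. bad SMARTS)."""


class UndefinedMetricError(BBBPError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class ROC-AUC)."""


class SplitError(BBBPError, ValueError):
    """A data split violates a precondition of the requested operation."""


class AccessGuardError(BBBPError, RuntimeError):
    """Raised when a selection procedure attempts to read held-out test rows."""
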