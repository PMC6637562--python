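"""Exception hierarchy for phosphogel."""


class PhosphogelError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PhosphogelError, ValueError):
    """Invalid simulation or run configuration; message names the offending field."""


class ParseError(PhosphogelError, ValueError):
    """Malformed spot-table input; message carries the 1-based data row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class DegenerateGelError(PhosphogelError, ValueError):
    """A gel image whose present spot volumes sum to zero cannot be normalized."""


class UndefinedPRError(PhosphogelError, ZeroDivisionError):
    """Phosphorylation rate is undefined when the total-stain volume is zero."""


class UndefinedFoldChangeError(PhosphogelError, ValueError):
    """Fold change is undefined when both group mean PRs are zero."""


class UnknownScenarioError(PhosphogelError, KeyError):
    """Requested simulation preset does not exist; message lists valid names."""
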