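"""Exception hierarchy shared across the package."""


class MRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRError):
    """A configuration value or column mapping is invalid."""


class ValidationError(MRError):
    """Input rows violate the summary-statistics invariants."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class AnalysisError(MRError):
    """An analysis step cannot proceed (empty intersection, too few SNPs...)."""


class NumericalError(MRError):
    """A numerical routine failed to find a valid solution."""
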