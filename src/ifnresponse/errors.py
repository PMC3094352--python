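"""Exception types raised across the pipeline."""


class IfnResponseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IfnResponseError, ValueError):
    """A simulation or analysis configuration field is invalid."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class DataError(IfnResponseError, ValueError):
    """Input records violate a structural requirement (missing signals,
    nonpositive background-corrected intensities, duplicated keys...)."""


class InsufficientDataError(IfnResponseError, ValueError):
    """Too few observations for the requested statistic."""


class ModelError(IfnResponseError, ValueError):
    """A model fit is degenerate (rank deficiency, empty group, all-zero counts)."""
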