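"""Exception hierarchy for lhda."""


class LHDAError(Exception):
    """Base class for all lhda errors."""


class ValidationError(LHDAError, ValueError):
    """Invalid argument values (negative weights, empty ranges, ...)."""


class DimensionError(ValidationError):
    """Mismatched array lengths or shapes."""


class InsufficientNeighborsError(LHDAError, ValueError):
    """A class does not contain enough eligible samples for the requested k."""

    def __init__(self, class_label, available, required):
        self.class_label = class_label
        self.available = available
        self.required = required
        super().__init__(
            f"class {class_label} has only {available} eligible sample(s); "
            f"{required} neighbor(s) required"
        )


class ConfigurationError(LHDAError, ValueError):
    """Dataset/config combination that cannot be trained or evaluated."""


class OptimizationError(LHDAError, RuntimeError):
    """An LP/optimization solve failed; carries the solver status."""

    def __init__(self, message, status=None):
        self.status = status
        super().__init__(message)


class SchemaError(LHDAError, ValueError):
    """A table is structurally unusable (missing label column, duplicate names)."""


class TableParseError(LHDAError, ValueError):
    """A table cell failed to parse; message carries row/column coordinates."""
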