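"""Exception types shared across the package."""


class FishDeltError(Exception):
    """Base class for package errors."""


class SchemaError(FishDeltError, ValueError):
    """A required column is missing or a schema mapping is unresolvable."""


class RowParseError(FishDeltError, ValueError):
    """A row-level value (year, flag) could not be parsed.

    Carries the offending row index in ``row``.
    """

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


class CrosswalkError(FishDeltError, LookupError):
    """An agency or anomaly category has no crosswalk entry."""


class EmptyDataError(FishDeltError, ValueError):
    """An operation that requires observations received none."""


class MissingDataError(FishDeltError, ValueError):
    """A stream or predictor has no usable values."""


class DegeneratePredictorError(FishDeltError, ValueError):
    """A predictor column is constant and cannot be standardized."""


class SpecError(FishDeltError, ValueError):
    """A parameter point or dataset does not conform to the model spec."""


class ShapeError(FishDeltError, ValueError):
    """Array dimensions are misaligned with the data or spec."""


class ConfigError(FishDeltError, ValueError):
    """An invalid generator or run configuration."""


class ConvergenceError(FishDeltError, RuntimeError):
    """A fit failed the convergence gate."""
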