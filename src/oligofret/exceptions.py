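"""Package-wide exception types."""


class OligofretError(Exception):
    """Base class for all package errors."""


class SchemaError(OligofretError):
    """A data file does not match the expected tabular schema."""


class FitFailureError(OligofretError):
    """A model fit did not converge or the data cannot constrain the model.

    Carries optional diagnostics (residuals, tried starts) in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class CalibrationError(OligofretError):
    """A required calibration value is missing or non-physical."""
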