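"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter or configuration field is invalid; message names the field."""


class CalibrationError(RuntimeError):
    """Calibration search failed; carries the best value found."""

    def __init__(self, message: str, best_value: float | None = None):
        super().__init__(message)
        self.best_value = best_value


class DegenerateLabelError(ValueError):
    """Classifier label contains a single class."""
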