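"""Package-wide exception types."""


class ValidationError(ValueError):
    """Invalid argument or inconsistent input data."""


class IntegrationError(RuntimeError):
    """Numerical integration produced a non-finite state."""


class CalibrationFailure(RuntimeError):
    """Conductivity/CV calibration could not reach its target."""


class DrugLookupError(KeyError):
    """Unknown (name, dose, variant) combination in the drug registry."""


class UndefinedBiomarker(RuntimeError):
    """A signal biomarker is undefined for the given input (e.g. silent lead)."""
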