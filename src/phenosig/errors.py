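"""Exception hierarchy shared across the pipeline."""


class PhenosigError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PhenosigError):
    """A file does not conform to its declared format."""


class ValidationError(PhenosigError):
    """Input violates a data-contract invariant."""


class ConfigError(PhenosigError):
    """A parameter value is outside its admissible range."""


class EmptyResultError(PhenosigError):
    """An operation removed every row/column and nothing is left to analyse."""


class CalibrationError(PhenosigError):
    """Score-concentration calibration is degenerate or under-determined."""


class FitError(PhenosigError):
    """A statistical model failed to converge or is separable."""
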