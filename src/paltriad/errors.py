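"""Exception hierarchy for the paltriad pipeline."""


class PalTriadError(Exception):
    """Base class for all paltriad errors."""


class ConfigurationError(PalTriadError):
    """A configuration field is invalid; the message names the field."""


class ValidationError(PalTriadError):
    """An input value violates a precondition (bad answer string, negative counts, ...)."""


class QualityControlError(PalTriadError):
    """A participant fails a data-quality rule (e.g. too few valid wear days)."""


class UndefinedCorrelationError(PalTriadError):
    """A correlation is requested for a zero-variance variable."""


class CollinearityError(PalTriadError):
    """Regression design matrix is numerically collinear."""
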