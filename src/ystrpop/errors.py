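"""Exception hierarchy shared across the package."""


class YstrpopError(Exception):
    """Base class for all package errors."""


class FormatError(YstrpopError, ValueError):
    """Malformed input text: bad allele token, wrong arity, duplicate ids."""


class ValidationError(YstrpopError, ValueError):
    """Structurally valid input that violates a precondition."""


class DegenerateInputError(ValidationError):
    """Input too small or too uniform for the statistic to be defined."""


class LookupError_(YstrpopError, KeyError):
    """Unknown locus or population label."""
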