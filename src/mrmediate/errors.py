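"""Exception hierarchy for mrmediate."""


class MrmediateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MrmediateError):
    """Invalid user configuration: bad column map, thresholds, block spec, ..."""


class EmptyInputError(MrmediateError):
    """An input panel contained zero valid rows."""


class ValidationError(MrmediateError):
    """A data structure violated one of its invariants (e.g. asymmetric LD matrix)."""


class HarmonizationError(MrmediateError):
    """Exposure and outcome panels share no usable variants."""


class InsufficientInstrumentsError(MrmediateError):
    """An estimator or diagnostic was given fewer SNPs than it requires."""


class DegenerateExposureError(MrmediateError):
    """All exposure effect sizes are zero; no causal ratio is defined."""


class MissingFieldError(MrmediateError):
    """A computation needs a field (eaf, n, ...) that is absent from the record."""
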