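"""Exception hierarchy.

Exit-code mapping used by the CLI: validation/schema/integrity errors -> 2,
data/configuration errors -> 3, numerical/model errors -> 4.
"""


class LRTError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(LRTError):
    """An invalid configuration value; the message names the field."""

    exit_code = 3


class ValidationError(LRTError):
    """Input data violates a structural precondition."""

    exit_code = 2


class IntegrityError(ValidationError):
    """Duplicate (patient, fraction, feature) records."""


class SchemaError(ValidationError):
    """Feature identifiers inconsistent with the attached schema."""


class RegistrationReferenceError(ValidationError):
    """Day-1 (reference) transform missing from a QC check."""


class DegenerateDesignError(ValidationError):
    """Trend design with no spread in fraction indices."""


class ScreeningError(LRTError):
    """Feature screening called with unusable labels (e.g. a single class)."""

    exit_code = 4


class ModelDegenerateError(LRTError):
    """A model whose parameters collapse (e.g. all SW weights zero)."""

    exit_code = 4
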