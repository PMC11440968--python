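"""Exception hierarchy shared across the package."""


class BBBScreenError(Exception):
    """Base class for all package errors."""


class ParseError(BBBScreenError):
    """A chemical structure could not be parsed."""


class SchemaError(BBBScreenError):
    """A tabular input is missing required columns."""


class ValidationError(BBBScreenError):
    """A data contract was violated (duplicate ids, misaligned tables, ...)."""


class ConfigurationError(BBBScreenError):
    """A model, rule or backend was misconfigured or unknown."""


class ScoringError(BBBScreenError):
    """A score could not be computed from the supplied profile."""


class DomainError(BBBScreenError):
    """A numeric input lies outside the mathematical domain of an equation."""
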