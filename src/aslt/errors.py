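"""Exception hierarchy for the toolkit."""


class AsltError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(AsltError):
    """An input table is missing a required column or flag."""


class TableParseError(AsltError):
    """A value in an input table could not be interpreted."""


class InsufficientDataError(AsltError):
    """Too few points (or temperatures) to fit the requested model."""


class DegenerateFitError(AsltError):
    """The fit is undefined, e.g. zero variance in the response."""


class DomainError(AsltError):
    """An input value lies outside the mathematical domain of the operation."""


class ConfigError(AsltError):
    """A configuration object violates its invariants."""
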