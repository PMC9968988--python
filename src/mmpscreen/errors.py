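"""Exception hierarchy for the screen-analysis pipeline.

Every pipeline-raised error derives from :class:`ScreenError` so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class ScreenError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(ScreenError):
    """A required column is missing from an input table."""


class ParseError(ScreenError):
    """A cell could not be parsed (carries the offending row number)."""


class ValidationError(ScreenError):
    """A table or record violates a domain invariant."""


class ConfigError(ScreenError):
    """An invalid configuration value."""


class MissingControlError(ScreenError):
    """A required control role has no wells on the plate."""


class StatisticError(ScreenError):
    """A statistic is undefined for the given inputs (e.g. empty hit set)."""


class UnknownCompoundError(ScreenError):
    """A compound id was not found in the annotation table."""
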