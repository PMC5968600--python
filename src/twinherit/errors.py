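"""Exception hierarchy for the twin-cohort analysis pipeline.

Every error raised by the package derives from :class:`TwinheritError`,
so callers (and the CLI) can catch one base class.
"""


class TwinheritError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(TwinheritError):
    """A refraction value is non-finite or violates sign conventions."""


class IncompleteRecordError(TwinheritError):
    """A subject is missing a required measurement (e.g. one eye)."""


class ConfigurationError(TwinheritError):
    """An unknown policy, model label, or invalid configuration value."""


class InsufficientDataError(TwinheritError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(TwinheritError):
    """Zero-variance or otherwise degenerate input to a statistic."""


class UndefinedTestError(TwinheritError):
    """A test statistic is undefined (e.g. a zero margin in a table)."""


class DataError(TwinheritError):
    """Invalid data content, e.g. an allele outside the declared set."""


class SeparationError(TwinheritError):
    """Logistic fit diverged: complete or quasi-complete separation."""


class UndefinedOddsRatioError(TwinheritError):
    """A 2x2 table has a zero cell and no correction was requested."""


class ValidationError(TwinheritError):
    """Cohort file failed schema validation; carries per-row messages."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__(
            "cohort validation failed:\n" + "\n".join(self.messages)
        )
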