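"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`InvalidInputError`
so the CLI can map it onto a single exit code.
"""


class ProtoscatterError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ProtoscatterError, ValueError):
    """Input outside the documented domain of an operation."""


class ConfigurationError(ProtoscatterError):
    """Malformed calibration, beam, or run configuration."""


class DegeneratePlanError(ProtoscatterError):
    """A plan whose geometry yields zero or undefined dose."""


class InsufficientDataError(ProtoscatterError):
    """Too few samples for the requested statistic."""


class FixtureError(ProtoscatterError):
    """A packaged data fixture is missing or fails its checksum."""


class MixedFieldError(InvalidInputError):
    """Single-predictor factor model applied to a field with both
    appreciable air and dense bone; the model is only valid when one
    heterogeneity type dominates."""
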