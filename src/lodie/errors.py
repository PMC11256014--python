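"""Exception hierarchy for the lodie pipeline.

Everything raised on purpose derives from :class:`LodieError`, so callers
can distinguish domain failures from programming errors.
"""


class LodieError(Exception):
    """Base class for all lodie-specific failures."""


class SchemaError(LodieError):
    """A required column or field is missing from an input table."""


class ParseError(LodieError):
    """A cell could not be parsed (non-numeric where a number is required)."""


class ValidationError(LodieError):
    """A value violates a domain invariant (e.g. non-positive concentration)."""


class ConfigurationError(LodieError):
    """An option combination is impossible (e.g. more required replicates than measured)."""


class NotEnoughDataError(LodieError):
    """Too few detected levels/points to attempt the requested fit."""


class DegenerateFitError(LodieError):
    """A regression cannot be computed (e.g. all x identical)."""


class NotAcceptedError(LodieError):
    """An operation requires an accepted linear range and got an unaccepted one."""


class NoDetectionError(LodieError):
    """The compound was not detected at any concentration level."""


class EstimatorUnavailableError(LodieError):
    """A LoD estimator's preconditions are not met for this series."""


class WorkflowError(LodieError):
    """An end-to-end workflow cannot produce its outputs."""
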