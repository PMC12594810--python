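"""Exception hierarchy for rheojet.

All package errors derive from :class:`RheojetError` so callers can catch
one base class; the subclasses mirror the failure categories of the
pipeline (schema, validation, protocol, range, configuration).
"""


class RheojetError(Exception):
    """Base class for all rheojet errors."""


class SchemaError(RheojetError):
    """A required column or field is missing from an input table."""


class ValidationError(RheojetError):
    """A value violates a type invariant (sign, monotonicity, length)."""


class ProtocolError(RheojetError):
    """A measurement does not follow the expected experimental protocol
    (e.g. a thixotropy trace missing its pre or post phase)."""


class InsufficientDataError(RheojetError):
    """Too few points for the requested fit."""


class RangeError(RheojetError):
    """A query point lies outside the measured span and extrapolation
    was not enabled."""


class AggregationError(RheojetError):
    """Replicates measured at inconsistent reference shear rates."""


class LabelingError(RheojetError):
    """Stability labels are inconsistent with the assumed ordering."""


class ConfigError(RheojetError):
    """Pipeline configuration is incomplete or contradictory."""


class PipelineError(RheojetError):
    """The pipeline cannot produce a result (e.g. every replicate was
    excluded by the quality-control gate)."""
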