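"""Exception hierarchy for dyadscope.

All validation failures raise a subclass of :class:`DyadscopeError` so callers
can distinguish bad inputs from genuine bugs.
"""


class DyadscopeError(Exception):
    """Base class for all dyadscope errors."""


class SchemaError(DyadscopeError):
    """File or table does not match the expected schema (columns, labels, shape)."""


class DataError(DyadscopeError):
    """Values violate a type invariant (NaN, non-monotone frames, out-of-range p)."""


class AlignmentError(DyadscopeError):
    """Two recordings cannot be combined (different sampling rates or lengths)."""


class BoundsError(DyadscopeError):
    """An event or block does not fit inside the recording it indexes."""


class ProtocolError(DyadscopeError):
    """Event table violates the experimental protocol (overlaps, duplicate trials)."""


class ParameterError(DyadscopeError):
    """Simulation or estimator parameters are invalid or unstable."""


class EmptyInputError(DyadscopeError):
    """An operation received no usable rows/blocks."""


class InsufficientDataError(DyadscopeError):
    """Not enough subjects/dyads/samples for the requested analysis."""


class DegenerateLabelError(DyadscopeError):
    """Classification labels contain a single class."""


class CVError(DyadscopeError):
    """Cross-validation specification cannot be satisfied by the grouping."""


class DesignError(DyadscopeError):
    """GLM design matrix is rank deficient or otherwise unusable."""


class ROIError(DyadscopeError):
    """Region-of-interest specification does not resolve to any parcels."""


class DegenerateInputError(DyadscopeError):
    """Zero-variance input where variation is required (regressors, correlations)."""


class DependencyError(DyadscopeError):
    """A pipeline stage is missing an upstream artifact."""
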