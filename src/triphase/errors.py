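"""Exception hierarchy for the tri-phase pipeline.

Every stage raises a subclass of :class:`TriphaseError` carrying the stage
name, so that pipeline drivers (and the CLI) can report which step failed.
"""


class TriphaseError(Exception):
    """Base class for all pipeline errors."""

    stage = "triphase"


class InvalidConfigError(TriphaseError):
    """A simulation or run configuration violates its invariants."""

    stage = "config"


class FormatError(TriphaseError):
    """An input trace violates the trace-format contract."""

    stage = "io"


class AlignmentError(TriphaseError):
    """Streams do not overlap, or a trace does not cover the requested span."""

    stage = "align"


class ImputationError(TriphaseError):
    """Soil-moisture imputation cannot run (too few points for the span)."""

    stage = "impute"


class DomainError(TriphaseError):
    """A value is outside the mathematical domain of an operation."""

    stage = "fit"


class DegenerateFitError(TriphaseError):
    """A regression has no information to estimate its slope."""

    stage = "fit"


class InsufficientDataError(TriphaseError):
    """Fewer points than a fit requires."""

    stage = "fit"


class InsufficientSpreadError(TriphaseError):
    """Predictor spread too small for a meaningful slope."""

    stage = "fit"


class NonDecreasingResponseError(TriphaseError):
    """The slow-phase slope is non-negative: growth does not decline with
    drying, so the water-deficit model does not apply."""

    stage = "fit"
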