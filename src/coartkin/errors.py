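"""Exception hierarchy for the coartkin pipeline."""


class CoartkinError(Exception):
    """Base class for all coartkin errors."""


class FormatError(CoartkinError):
    """A trial/layout file does not conform to the expected dialect."""


class ValidationError(CoartkinError):
    """Input data violates a structural invariant (e.g. non-monotone time)."""


class PreprocessingError(CoartkinError):
    """The smoothing/segmentation stage cannot process a trial."""


class OnsetUndetectableError(PreprocessingError):
    """No sample below the onset threshold precedes the first qualifying peak."""


class MeasureUndefinedError(CoartkinError):
    """A kinematic measure is undefined for this profile (e.g. no peaks)."""


class OptimizationError(CoartkinError):
    """Via-point optimization failed to converge within the restart budget."""


class DesignError(CoartkinError):
    """A statistical design requirement is not met (cells too small, etc.)."""
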