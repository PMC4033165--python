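"""Exception types raised across the pipeline."""


class PerceptTrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PerceptTrackError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDesignError(PerceptTrackError, ValueError):
    """The GLM design matrix cannot support the percept contrast
    (e.g. a timeline containing a single perceptual state)."""


class InvalidTrainingSetError(PerceptTrackError, ValueError):
    """Classifier training data contains fewer than two classes."""


class EmptySelectionError(PerceptTrackError, ValueError):
    """A selection step produced an empty feature set."""


class InvalidSessionError(PerceptTrackError, ValueError):
    """A session does not meet the structural requirements of a protocol
    (e.g. too few runs for leave-one-run-out cross-validation)."""


class MissingBaselineError(PerceptTrackError, RuntimeError):
    """Online zero-centering was requested before a baseline was stored."""
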