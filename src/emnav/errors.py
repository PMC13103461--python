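"""Exception hierarchy for the navigation pipeline.

Every error raised by emnav derives from :class:`NavigationError`, so callers
can catch pipeline failures without masking programming errors.
"""


class NavigationError(Exception):
    """Base class for all emnav errors."""


class FrameError(NavigationError):
    """Coordinate frames do not chain (e.g. composing mismatched transforms)."""


class SynchronizationError(NavigationError):
    """Timestamps of two pose samples differ by more than the tolerance."""


class CorrespondenceError(NavigationError):
    """Paired point sets disagree in cardinality or naming."""


class DegenerateGeometryError(NavigationError):
    """Point configuration is insufficient for the operation (collinear, < 3, empty)."""


class AcquisitionTimeoutError(NavigationError):
    """Probe stream ended before a stable measurement series completed."""


class InstabilityError(NavigationError):
    """Acquisition exceeded the configured maximum number of restarts."""


class RegistrationRejectedError(NavigationError):
    """All registration attempts were rejected by the acceptance policy.

    Carries the best attempt seen so the caller can still inspect it.
    """

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class SchemaError(NavigationError):
    """A file does not conform to the declared schema."""


class SpecError(NavigationError):
    """A simulator/phantom specification is infeasible or out of range."""
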