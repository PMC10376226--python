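"""Exception hierarchy shared across the package."""


class HopwaveError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HopwaveError):
    """A parameter set violates its stated invariants."""


class TrialFormatError(HopwaveError):
    """A trial file does not conform to the expected CSV dialect."""


class EventNotFoundError(HopwaveError):
    """A phase-boundary event could not be located in the signal."""


class SegmentationError(HopwaveError):
    """Detected phase events violate the required t0 < t1 < t2 < t3 ordering."""


class CollinearityError(HopwaveError):
    """Candidate predictors are too collinear for a stable regression fit."""
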