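"""Exception types raised across the pipeline."""


class BoutmapError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BoutmapError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidSceneError(BoutmapError, ValueError):
    """A synthetic scene is inconsistent (e.g. footprint outside the frame)."""


class UndefinedAngleError(BoutmapError, ValueError):
    """Bend angle is undefined (swim-bladder and tail-tip points coincide)."""


class EstimationFailedError(BoutmapError, RuntimeError):
    """Bleed-through estimation has no usable red-positive pixels."""


class DegenerateBaselineError(BoutmapError, ValueError):
    """A fluorescence baseline F0 <= 0 makes dF/F undefined."""


class EmptyEventSetError(BoutmapError, ValueError):
    """No admissible events: the trace cannot be windowed or classified."""
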