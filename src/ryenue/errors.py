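"""Exception types shared across the pipeline."""


class RyenueError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(RyenueError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class EmptyMaskError(RyenueError, ValueError):
    """Shape features were requested for a mask with no foreground pixels."""


class FrameOverflowError(RyenueError, ValueError):
    """A rendered plant projection does not fit inside the image frame."""


class ConvergenceError(RyenueError, RuntimeError):
    """A model fit failed to converge or produced a singular system."""
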