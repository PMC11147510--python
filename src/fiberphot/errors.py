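"""Exception hierarchy shared across the package."""


class FiberphotError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FiberphotError, ValueError):
    """An input violated a documented precondition or invariant."""


class RecordingCorruptionError(FiberphotError, ValueError):
    """An interleaved recording broke the channel-alternation invariant."""


class BaselineFitError(FiberphotError, RuntimeError):
    """Nonlinear baseline fit failed to converge or was rejected."""


class ZeroVarianceError(ValidationError):
    """A standardization support had zero (or numerically zero) variance."""


class PipelineError(FiberphotError, RuntimeError):
    """A preprocessing stage failed; the message names the stage."""
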