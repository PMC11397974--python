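"""Exception hierarchy shared by all pipeline stages."""


class HystereonError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(HystereonError, ValueError):
    """A precondition on an operation's arguments was violated."""


class DegenerateInputError(HystereonError, ValueError):
    """Input is syntactically valid but numerically degenerate (zero variance,
    vanishing Fourier coefficient, ...)."""


class CoverageError(HystereonError, ValueError):
    """A stream does not cover the time windows it is being aligned to."""


class FitFailureError(HystereonError, RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class TrainingError(HystereonError, RuntimeError):
    """Sequence-model training diverged (NaN/Inf loss)."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class QualityError(HystereonError, RuntimeError):
    """Signal quality too poor for the requested derivation (e.g. undetectable
    ECG beats over too large a fraction of a window)."""


class ConfigError(HystereonError, ValueError):
    """Run configuration is invalid (unknown key, bad value)."""
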