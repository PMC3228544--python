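"""Exception types shared across the package."""


class RidgeSigError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RidgeSigError, ValueError):
    """Invalid input data or parameters."""


class SingularityError(RidgeSigError, ValueError):
    """A required matrix inverse does not exist (e.g. lambda = 0 with m > n)."""


class ConvergenceError(RidgeSigError, RuntimeError):
    """Iterative fitting failed to converge or diverged."""
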