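"""Exception hierarchy for mvgmdr."""


class GmdrError(Exception):
    """Base class for all mvgmdr errors."""


class FormatError(GmdrError, ValueError):
    """A file does not conform to the expected dialect."""


class AlignmentError(GmdrError, ValueError):
    """Sample identifiers cannot be reconciled across inputs."""


class ConvergenceError(GmdrError, RuntimeError):
    """Iterative fitting failed to converge.

    Carries the last iterate (if any) in ``last_fit`` so callers can inspect
    the state at failure.
    """

    def __init__(self, message, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


class StandardizationError(GmdrError, ValueError):
    """Residual standardization is undefined (zero variance function)."""


class DegenerateModelError(GmdrError, ValueError):
    """A penetrance model with a high-risk group of frequency 0 or 1."""


class DegenerateNullError(GmdrError, ValueError):
    """A null distribution with zero spread cannot support a Z approximation."""


class EmptyTableError(GmdrError, ValueError):
    """No individual could be assigned to any cell of the attribute table."""


class FoldError(GmdrError, ValueError):
    """A cross-validation fold has no usable training observations."""
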