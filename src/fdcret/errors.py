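"""Exception types shared across the package."""


class FdcretError(Exception):
    """Base class for package-specific errors."""


class CalibrationError(FdcretError):
    """Rebinding calibration could not reach the requested anchors.

    Carries ``best_residual`` (the smallest relative anchor residual seen
    across the candidate grid) when available.
    """

    def __init__(self, message, best_residual=None):
        super().__init__(message)
        self.best_residual = best_residual


class InfeasibleAnchorsError(CalibrationError):
    """Calibration anchors violate monotonicity (half-life must be
    non-decreasing in receptor density)."""


class GridTooShortError(FdcretError):
    """A survival curve never reached the requested level within its time
    grid; extend the grid."""


class FitError(FdcretError):
    """A nonlinear fit failed to converge or the data were degenerate."""
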