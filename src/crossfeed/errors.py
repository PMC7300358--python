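"""Exception hierarchy shared across the package."""


class CrossfeedError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CrossfeedError, ValueError):
    """A model, regime, or design parameter violates its constraints."""


class InvalidStateError(CrossfeedError, ValueError):
    """A system state violates non-negativity or range constraints."""


class InvalidInputError(CrossfeedError, ValueError):
    """Malformed input data (too few points, empty grid, ...)."""


class IntegrationError(CrossfeedError, RuntimeError):
    """The ODE integrator failed; carries the last good state if available."""

    def __init__(self, message, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


class ExtinctCultureError(CrossfeedError, ValueError):
    """An operation requiring live cells was applied to an empty culture."""


class FitFailureError(CrossfeedError, RuntimeError):
    """Nonlinear least squares failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
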