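"""Exception hierarchy shared across the package."""


class BubstonError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(BubstonError):
    """Raised when a unit conversion mixes incompatible dimensions."""


class DomainError(BubstonError, ValueError):
    """A physical parameter is outside its admissible domain."""


class UsageError(BubstonError, ValueError):
    """An operation was called with an inconsistent argument combination."""


class NoRealEigenfrequencyError(BubstonError):
    """The linearized restoring force is negative: no real oscillation frequency.

    Carries the (negative) squared frequency so the caller can inspect how far
    past the stability threshold the configuration sits.
    """

    def __init__(self, omega_sq: float, message: str | None = None):
        self.omega_sq = omega_sq
        super().__init__(
            message or f"no real eigenfrequency: omega^2 = {omega_sq:.6g} s^-2 < 0"
        )


class BubbleCollapseError(BubstonError):
    """Radial integration drove the bubble radius toward zero.

    ``last_state`` is a ``(t, R, Rdot)`` tuple with the last valid solver state.
    """

    def __init__(self, last_state, message: str | None = None):
        self.last_state = last_state
        super().__init__(message or f"bubble collapse at t = {last_state[0]:.6g} s")


class SolverError(BubstonError):
    """The ODE solver failed before reaching the end of the time span."""

    def __init__(self, last_state, detail: str = ""):
        self.last_state = last_state
        super().__init__(f"radial integration failed: {detail}")


class NoOscillationError(BubstonError):
    """A trajectory contains no usable oscillatory content."""


class DegenerateDataError(BubstonError, ValueError):
    """Statistical comparison is impossible (e.g. zero variance in both groups)."""
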