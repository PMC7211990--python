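"""Exception hierarchy shared across the package."""


class RbcGasError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RbcGasError, ValueError):
    """An argument is outside its physical/mathematical domain."""


class ParameterizationError(RbcGasError):
    """A requested (p50, hill_n, k_d, ...) combination cannot be realized.

    Carries a ``diagnostic`` attribute describing what was attempted and
    which constraint failed.
    """

    def __init__(self, message: str, diagnostic: dict | None = None):
        super().__init__(message)
        self.diagnostic = diagnostic or {}


class SolverFailure(RbcGasError):
    """A numerical integration or root-find did not converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InfeasibleTarget(RbcGasError):
    """A fit target lies outside the reachable range (e.g. below the
    reaction-limited floor of the unloading time constant)."""

    def __init__(self, message: str, floor: float | None = None):
        super().__init__(message)
        self.floor = floor


class UnidentifiableError(RbcGasError):
    """The data carry no information about the requested parameter
    (e.g. spatially uniform pH cannot constrain a diffusivity)."""


class DegenerateCalibrationError(DomainError):
    """Calibration endpoints coincide (r_oxy == r_deoxy)."""


class EmptyPopulationError(RbcGasError):
    """No usable (converged) observations in a population operation."""


class SchemaError(RbcGasError):
    """A table is missing required columns or is otherwise malformed."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class PhysicallyInconsistentError(RbcGasError):
    """A derived quantity has an impossible sign/magnitude; reported, not
    silently clamped."""
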