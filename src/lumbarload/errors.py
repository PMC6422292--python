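"""Exception hierarchy for the simulator."""


class LumbarLoadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LumbarLoadError):
    """Constants/configuration violate a structural invariant."""


class ValidationError(LumbarLoadError):
    """An input value is outside its admissible domain."""


class GeometryError(LumbarLoadError):
    """Degenerate or unreachable geometric construction."""


class InfeasibleProblemError(LumbarLoadError):
    """The recruitment problem admits no nonnegative solution."""


class SolverConvergenceError(LumbarLoadError):
    """The recruitment optimizer failed to meet the residual contract."""
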