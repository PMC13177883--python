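"""Exception hierarchy shared across the package."""


class CpceaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CpceaError, ValueError):
    """A configuration object or file violates its invariants.

    The message always names the offending field(s).
    """


class InputError(CpceaError, ValueError):
    """Invalid data passed to a computation (empty cohort, too few points, ...)."""


class EstimationError(CpceaError, RuntimeError):
    """Estimation cannot proceed (rank deficiency, insufficient sample, ...)."""


class UndefinedRatioError(CpceaError, ZeroDivisionError):
    """Incremental effect too close to zero for a meaningful ICER."""


class ParameterError(CpceaError, ValueError):
    """Microsimulation parameters are infeasible (e.g. transition row > 1)."""
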