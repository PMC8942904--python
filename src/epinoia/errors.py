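"""Exception hierarchy shared across the package."""


class EpinoiaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EpinoiaError):
    """An invalid field in a simulation or run configuration."""


class InputError(EpinoiaError):
    """Invalid user-supplied data (ids, shapes, factor levels)."""


class DegenerateArchitectureError(EpinoiaError):
    """A genetic architecture that cannot realize its target variances."""


class LayoutError(EpinoiaError):
    """Field layout cannot accommodate the requested plots."""


class EmptyPanelError(EpinoiaError):
    """All markers removed by quality control; downstream matrices undefined."""


class DegeneratePanelError(EpinoiaError):
    """Marker panel carries no variation (all coefficients zero)."""


class IdMismatchError(EpinoiaError):
    """Lines present in the phenotype table but missing from a matrix."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class ConvergenceError(EpinoiaError):
    """REML failed to reach a stationary point; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SingularSystemError(EpinoiaError):
    """A linear system required by the model is singular."""


class UndefinedStatisticError(EpinoiaError):
    """A ratio or correlation is undefined for the given inputs."""
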