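"""Exception hierarchy for the milestoning toolkit."""


class VTMMError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(VTMMError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateSamplingError(VTMMError):
    """A cell has no usable sampling time; names the offending cell."""


class NoUniqueSolutionError(VTMMError):
    """The cell graph is disconnected; the balance equation has no unique
    stationary solution.  ``components`` lists the connected components."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []


class InconsistentStatisticsError(VTMMError):
    """Transition counts exist for a milestone with zero residence time."""


class UnreachableMilestoneError(VTMMError):
    """The target milestone cannot be reached from some milestone, so the
    first-passage linear system is singular."""


class UnstableIntegrationError(VTMMError):
    """The stochastic integrator diverged (time step too large)."""


class SelectionError(VTMMError):
    """An atom selector matched zero or several atoms.  ``matches`` carries
    the offending match list."""

    def __init__(self, message, matches=None):
        super().__init__(message)
        self.matches = matches if matches is not None else []


class QuadratureError(VTMMError):
    """A numerical quadrature failed to converge to the requested accuracy."""
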