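"""Exception hierarchy for pamsens."""


class PamError(Exception):
    """Base class for all pamsens errors."""


class ModelBuildError(PamError):
    """Raised when a model cannot be assembled from its parts."""


class InvalidSectorConfigError(ModelBuildError):
    """Raised when sector parameters imply a negative protein budget."""


class InvalidBoundsError(ModelBuildError):
    """Raised when a reaction has lower bound > upper bound."""


class IsozymeError(ModelBuildError):
    """Raised when more than one enzyme claims the same reaction.

    The enzyme-coupling matrix is diagonal: each catalyzed reaction is
    coupled to exactly one enzyme. Isozymes are outside the formulation.
    """


class SolverError(PamError):
    """Raised when the LP backend fails for a reason other than
    infeasibility or unboundedness."""


class InfeasibleProblemError(SolverError):
    """Raised when the LP has no feasible point. Carries a ``hint``
    attribute naming a likely cause when one can be identified."""

    def __init__(self, message: str, hint: str | None = None):
        super().__init__(message if hint is None else f"{message} ({hint})")
        self.hint = hint


class UnboundedProblemError(SolverError):
    """Raised when the LP objective is unbounded above."""


class NonOptimalSolutionError(PamError):
    """Raised when an operation requires an optimal solution but was
    given one with a different status."""


class ZeroObjectiveError(PamError):
    """Raised when sensitivity normalization is requested at an optimum
    with objective value zero (normalization undefined)."""
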