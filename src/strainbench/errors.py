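"""Exception hierarchy for the workbench.

All errors raised by strainbench derive from :class:`StrainbenchError` so
callers can catch the library's failures with a single clause. Simulation
routines never raise for infeasible/unbounded LPs — those are mapped into
``SimulationResult.status`` — so the exceptions here signal contract
violations, malformed inputs, or missing solver capabilities.
"""


class StrainbenchError(Exception):
    """Base class for all strainbench errors."""


class ModelFormatError(StrainbenchError):
    """A model file could not be parsed; the message names the offending element."""


class NoObjectiveError(ModelFormatError):
    """The loaded model declares no objective reaction."""


class ValidationError(StrainbenchError):
    """A model, network, or problem violates a structural invariant."""


class ConstraintConflictError(StrainbenchError):
    """Merged bounds left a reaction with lower bound above upper bound."""

    def __init__(self, reaction_id: str, lb: float, ub: float):
        self.reaction_id = reaction_id
        self.lb = lb
        self.ub = ub
        super().__init__(
            f"conflicting bounds on reaction '{reaction_id}': ({lb}, {ub})"
        )


class GPRParseError(StrainbenchError):
    """A GPR or regulatory rule string is malformed.

    ``position`` is the character offset of the offending token.
    """

    def __init__(self, message: str, position: int = -1):
        self.position = position
        if position >= 0:
            message = f"{message} (at position {position})"
        super().__init__(message)


class CapabilityError(StrainbenchError):
    """The configured solver backend lacks a capability (e.g. quadratic MOMA)."""


class ConfigurationError(StrainbenchError):
    """A run configuration or problem definition is invalid."""


class DecodeError(StrainbenchError):
    """A candidate references a target unknown to its problem."""
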