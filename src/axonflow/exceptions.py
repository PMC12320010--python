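"""Exception hierarchy.

All package errors derive from :class:`AxonflowError` so callers can catch
one base class; subclasses mirror the failure modes of the pipeline stages.
"""


class AxonflowError(Exception):
    """Base class for all package errors."""


class ParameterError(AxonflowError, ValueError):
    """An argument is outside its documented domain."""


class InfeasibleSubstrateError(AxonflowError):
    """Axon + myelin area exceeds the tile area."""


class EmptySubstrateError(AxonflowError):
    """An operation that needs axons received a voxel with none."""


class ProtocolFormatError(AxonflowError):
    """Malformed acquisition table (bval/bvec/JSON)."""


class PresetLookupError(AxonflowError, KeyError):
    """Unknown built-in protocol preset name."""


class DesignMatrixError(AxonflowError):
    """Model fit is underdetermined for the given protocol."""


class AccuracyError(AxonflowError):
    """A series/quadrature failed to converge to the requested tolerance."""


class NumericalStabilityError(AxonflowError):
    """A density or loss evaluated to a non-finite value."""


class FreezePlanError(AxonflowError, ValueError):
    """A fine-tuning freeze plan names components that do not exist."""


class RosterError(AxonflowError):
    """Cross-validation constraints are infeasible for the subject roster."""


class SelectionError(AxonflowError):
    """Model selection received an empty candidate set."""


class DependencyError(AxonflowError):
    """A pipeline stage is missing an upstream artifact."""
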