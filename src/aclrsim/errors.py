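"""Exception hierarchy shared across the toolkit."""


class ACLRSimError(Exception):
    """Base class for all toolkit errors."""


class InvalidParameterError(ACLRSimError, ValueError):
    """A physical parameter is outside its admissible range."""


class InvalidLandmarksError(ACLRSimError, ValueError):
    """Tunnel landmarks are degenerate (coincident or otherwise unusable)."""


class InvalidScheduleError(ACLRSimError, ValueError):
    """An axial element-density schedule is inconsistent with the requested length."""


class EmptyProfileError(ACLRSimError, RuntimeError):
    """Cross-section slicing produced no valid station."""


class DrillingError(ACLRSimError, RuntimeError):
    """Tunnel drilling failed (breached wall, non-watertight result, ...)."""


class OsseousWallViolationError(ACLRSimError, ValueError):
    """Double-bundle tunnels intersect: the bone bridge between them is destroyed."""


class TwistError(ACLRSimError, RuntimeError):
    """Bundle twisting produced interpenetrating bundles."""


class SelfIntersectionError(ACLRSimError, RuntimeError):
    """Sweeping a mesh along a path would self-intersect (curvature too tight)."""


class SingularPoseError(ACLRSimError, RuntimeError):
    """Grood-Suntay decomposition is singular (femoral ML parallel to tibial SI)."""


class AssemblyError(ACLRSimError, ValueError):
    """Knee model assembly inputs are inconsistent with the requested variant."""


class ExportError(ACLRSimError, RuntimeError):
    """Writing a solver input or mesh file failed."""


class ConvergenceError(ACLRSimError, RuntimeError):
    """Quasi-static equilibrium iteration did not converge."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


class ConfigurationError(ACLRSimError, ValueError):
    """A configuration value (material tag, protocol entry, ...) is unknown."""


class NumericalDegeneracyError(ACLRSimError, RuntimeError):
    """A geometric quantity degenerated (zero-length spring chord, ...)."""


class DegenerateShapeWarning(UserWarning):
    """A mesh has no well-separated principal axis (near-spherical shape)."""
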