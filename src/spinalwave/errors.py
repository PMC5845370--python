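"""Exception hierarchy for spinalwave.

All package errors derive from :class:`SpinalwaveError` so callers can catch
the whole family with one clause.
"""


class SpinalwaveError(Exception):
    """Base class for all spinalwave errors."""


class OrderingError(SpinalwaveError):
    """Axial station coordinates are not strictly increasing."""


class GeometryError(SpinalwaveError):
    """Layer radii violate nesting or another geometric invariant."""


class InsufficientDataError(SpinalwaveError):
    """Too few stations for the requested operation."""


class SingularModulusError(SpinalwaveError):
    """Poisson ratio of 0.5 makes the elastic moduli singular."""


class PhysicsError(SpinalwaveError):
    """A derived mechanical quantity is non-physical (e.g. not positive definite)."""


class StabilityError(SpinalwaveError):
    """Explicit time step violates the CFL bound."""

    def __init__(self, msg: str, suggested_dt: float | None = None):
        super().__init__(msg)
        self.suggested_dt = suggested_dt


class SolverBlowupError(SpinalwaveError):
    """Time marching produced non-finite fields."""


class ResolutionError(SpinalwaveError):
    """Wavefronts did not separate well enough to estimate speeds."""


class UsageError(SpinalwaveError):
    """An operation was called on an incompatible input."""


class AlignmentError(SpinalwaveError):
    """Fields are not defined on a common grid."""


class ConfigurationError(SpinalwaveError):
    """Invalid or degenerate model configuration."""


class PerturbationError(SpinalwaveError):
    """Random perturbation could not produce a valid geometry."""


class BinningError(SpinalwaveError):
    """Stress binning failed (e.g. grid coarser than the bin width)."""


class ConfigError(SpinalwaveError):
    """Run configuration file is invalid; message lists every offender."""


class ThinWallWarning(UserWarning):
    """Cord annulus wall is so thin that the compliance diverges."""
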