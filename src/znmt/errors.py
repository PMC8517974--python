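"""Exception hierarchy.

``ValidationError`` covers malformed inputs and configs (CLI exit code 2);
``ComputationError`` covers failures arising during a computation itself
(CLI exit code 3).
"""


class ZnmtError(Exception):
    """Base class for all package errors."""


class ValidationError(ZnmtError):
    """Malformed input, config, or precondition violation."""


class ComputationError(ZnmtError):
    """A computation failed (divergence, degenerate data, ...)."""


class InvalidClusterError(ValidationError):
    """A cluster graph violates its degree invariants."""


class InfeasibleStoichiometryError(ValidationError):
    """No bridging/terminal split exists for the requested composition."""


class InvalidOccupancyError(ValidationError):
    """A ligand is claimed by more than one cluster."""


class UndefinedDrmsdError(ComputationError):
    """The reference structure yields an empty distance-pair list."""


class IntegrationError(ComputationError):
    """Langevin integration diverged."""


class TrajectoryFormatError(ValidationError):
    """A coordinate file is malformed."""


class GridMismatchError(ValidationError):
    """Spectra or histograms are not on a common grid."""
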