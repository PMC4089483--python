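"""Exception hierarchy.

Input problems (bad files, bad parameters) and empty-density findings are
distinguished so the CLI can exit with different codes.
"""


class BlobidError(Exception):
    """Base class for all package errors."""


class FormatError(BlobidError):
    """Unreadable or malformed input file."""


class UnsupportedCellError(FormatError):
    """Map cell is non-orthogonal; only orthogonal P1 cells are handled."""


class OutOfBoundsError(BlobidError):
    """A point lies outside the map bounding box."""


class InvalidSceneError(BlobidError):
    """Synthetic scene description is unusable (e.g. no atoms)."""


class EmptyBlobError(BlobidError):
    """No density above the placement floor near the seed point."""


class EmptyInputError(BlobidError):
    """An operation received an empty point set."""


class TooSmallError(BlobidError):
    """Input below the minimum size an operation requires."""


class ParameterError(BlobidError):
    """Invalid configuration or call parameter."""


class TopologyError(BlobidError):
    """Bond perception produced a disconnected or degenerate graph."""


class DegenerateAxesError(BlobidError):
    """Principal axes undefined (collinear or coincident points)."""


class FitError(BlobidError):
    """Feature-normalization fit failed (e.g. zero-variance feature)."""


class InsufficientRegionError(BlobidError):
    """Too few masked voxels to compute a real-space correlation."""
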