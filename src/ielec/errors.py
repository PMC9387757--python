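"""Exception hierarchy shared across the package."""


class IelecError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(IelecError):
    """Array or point-set shape is incompatible with the operation."""


class FrameError(IelecError):
    """Coordinate-frame tags of the operands do not line up."""


class KindError(IelecError):
    """Volume kind (scalar vs label) is wrong for the operation."""


class BoundsError(IelecError):
    """A seed or sampling region falls outside the volume grid."""


class NameError_(IelecError):
    """A channel name is not in the montage's predetermined list."""


class FormatError(IelecError):
    """A text file (TSV, LUT, OFF, config) is malformed."""


class TopologyError(IelecError):
    """A surface mesh is open or mis-oriented where a closed one is required."""


class StateError(IelecError):
    """An operation was applied to a contact in the wrong status."""


class OverlapError(IelecError):
    """Volume fields of view do not overlap enough to register.

    Raised when, after seeding, fewer than the required fraction of fixed
    voxels map inside the moving volume; a manual pre-alignment passed as
    ``initial`` is the usual fix.
    """


class SpecError(IelecError):
    """A phantom or pipeline specification is internally inconsistent."""
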