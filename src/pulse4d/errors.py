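"""Exception and warning hierarchy.

All pipeline stages raise subclasses of :class:`Pulse4DError` so callers can
distinguish domain failures (bad geometry, leaking cuts, degenerate curves)
from programming errors.
"""


class Pulse4DError(Exception):
    """Base class for all domain errors."""


class InvalidArgumentError(Pulse4DError, ValueError):
    """A parameter violates its precondition (e.g. low >= high threshold)."""


class InvalidGeometryError(Pulse4DError):
    """Degenerate geometry: collinear neck points, absent neck, etc."""


class OutOfBoundsError(Pulse4DError):
    """A rigid motion would move the object outside the voxel grid."""


class EmptyMeshError(Pulse4DError):
    """Isosurface extraction found no surface (empty mask / no iso crossing)."""


class OpenMeshError(Pulse4DError):
    """A mesh operation requiring watertightness found boundary edges."""

    def __init__(self, boundary_edge_count: int):
        self.boundary_edge_count = int(boundary_edge_count)
        super().__init__(
            f"mesh is not watertight: {boundary_edge_count} boundary edge(s)"
        )


class FocusError(Pulse4DError):
    """Too few source vertices inside the ICP focus sphere."""


class SeedError(Pulse4DError):
    """Seed voxel/point does not hit any labelled component."""


class LeakError(Pulse4DError):
    """The cut surface failed to separate dome from parent vessel."""


class DegenerateCurveError(Pulse4DError):
    """A constant curve cannot be min-max normalized (reported as flat)."""


class UndefinedICCError(Pulse4DError):
    """ICC is undefined (zero total variance in the ratings matrix)."""


class EmptySegmentationWarning(UserWarning):
    """Thresholding produced an empty mask on all phases."""


class OrientationWarning(UserWarning):
    """Mesh orientation was inward and has been flipped."""


class ConvergenceWarning(UserWarning):
    """Iterative procedure hit its iteration cap before the tolerance."""
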