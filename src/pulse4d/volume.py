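"""4D CT angiography volume container.

Voxels are indexed ``(x, y, z, phase)``; indices are 0-based and the world
coordinate of a voxel *center* is ``origin + index * spacing`` (mm).  The
phase axis samples the cardiac (R-R) cycle, conventionally 10 steps of 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError


@dataclass
class CTVolume4D:
    """Hounsfield-unit voxel grid over three spatial axes plus cardiac phase."""

    voxels: np.ndarray                      # (X, Y, Z, P), HU
    spacing: np.ndarray                     # (3,) mm per spatial axis
    origin: np.ndarray = field(default=None)  # (3,) mm of voxel (0,0,0) center

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise InvalidArgumentError(
                f"expected a 4D (x, y, z, phase) array, got ndim={self.voxels.ndim}"
            )
        if self.voxels.shape[3] < 2:
            raise InvalidArgumentError("need at least 2 cardiac phases")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise InvalidArgumentError("spacing must be strictly positive")
        self.origin = (
            np.zeros(3) if self.origin is None
            else np.asarray(self.origin, dtype=float).reshape(3)
        )

    @property
    def n_phases(self) -> int:
        return self.voxels.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def phase(self, p: int) -> np.ndarray:
        """3D HU array of one cardiac phase."""
        return self.voxels[..., p]

    def index_to_world(self, index) -> np.ndarray:
        """World mm coordinate(s) of voxel-center index/indices."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def world_to_index(self, world) -> np.ndarray:
        """Fractional voxel index of world mm coordinate(s)."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing
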