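"""Threshold segmentation of the vascular lumen.

Contrast-enhanced lumen is separated from cerebrospinal fluid / soft tissue by
a Hounsfield-unit band (default 160 to 890 HU, inclusive at both ends),
applied independently per cardiac phase.  A volume of interest (VOI) crop and
a seeded connected-component filter stand in for the interactive clean-up of
a workstation workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import EmptySegmentationWarning, InvalidArgumentError, SeedError
from .volume import CTVolume4D

#: 26-connectivity structuring element (keeps thin oblique vessels connected)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LumenMask4D:
    """Per-phase binary lumen mask on the source grid, with the HU band used."""

    mask: np.ndarray            # (X, Y, Z, P) bool
    low: float
    high: float
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def n_phases(self) -> int:
        return self.mask.shape[3]

    def phase(self, p: int) -> np.ndarray:
        return self.mask[..., p]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def masked_volume_mm3(self, p: int) -> float:
        """Binary-mask volume of one phase (voxel count x voxel volume)."""
        return float(self.mask[..., p].sum()) * self.voxel_volume_mm3()


@dataclass(frozen=True)
class VOI:
    """Axis-aligned box in voxel indices: inclusive start, exclusive end."""

    start: tuple[int, int, int]
    end: tuple[int, int, int]

    def validate(self, grid_shape) -> None:
        s, e = np.asarray(self.start), np.asarray(self.end)
        if np.any(s >= e):
            raise InvalidArgumentError("VOI start must be < end on all axes")
        if np.any(s < 0) or np.any(e > np.asarray(grid_shape)):
            raise InvalidArgumentError("VOI must lie within the grid")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(s, e) for s, e in zip(self.start, self.end))


def threshold_lumen(volume: CTVolume4D, low: float = 160.0, high: float = 890.0) -> LumenMask4D:
    """Band-threshold each phase: voxel kept iff ``low <= HU <= high``.

    An all-empty result is a warning (empty-segmentation), not a failure.
    """
    if low >= high:
        raise InvalidArgumentError(f"low threshold ({low}) must be < high ({high})")
    mask = (volume.voxels >= low) & (volume.voxels <= high)
    if not mask.any():
        warnings.warn(
            f"thresholding [{low}, {high}] HU produced an empty mask on all phases",
            EmptySegmentationWarning,
        )
    return LumenMask4D(mask=mask, low=low, high=high,
                       spacing=volume.spacing, origin=volume.origin)


def crop_voi(mask: LumenMask4D, voi: VOI) -> LumenMask4D:
    """Clear all voxels outside the VOI; grid shape and metadata preserved."""
    voi.validate(mask.mask.shape[:3])
    out = np.zeros_like(mask.mask)
    sl = voi.slices()
    out[sl[0], sl[1], sl[2], :] = mask.mask[sl[0], sl[1], sl[2], :]
    if not out.any():
        warnings.warn("VOI crop removed all masked voxels", EmptySegmentationWarning)
    return replace(mask, mask=out)


def keep_component(mask: LumenMask4D, seed_point: tuple[int, int, int]) -> LumenMask4D:
    """Keep, per phase, only the 26-connected component containing the seed.

    The seed voxel must be masked at phase 0; for phases where that exact
    voxel is unmasked the seed is transferred to the nearest masked voxel.
    """
    seed = tuple(int(i) for i in seed_point)
    if not mask.mask[seed + (0,)]:
        raise SeedError(f"seed voxel {seed} is not masked at phase 0")
    out = np.zeros_like(mask.mask)
    for p in range(mask.n_phases):
        m = mask.mask[..., p]
        if not m.any():
            continue
        labels, _ = ndimage.label(m, structure=_STRUCT_26)
        lab = labels[seed]
        if lab == 0:
            # transfer seed to the nearest masked voxel of this phase
            _, idx = ndimage.distance_transform_edt(
                ~m, sampling=mask.spacing, return_indices=True
            )
            lab = labels[tuple(idx[:, seed[0], seed[1], seed[2]])]
        out[..., p] = labels == lab
    return replace(mask, mask=out)
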