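"""Per-phase triangulated lumen surfaces and enclosed-volume computation.

The sub-voxel sensitivity of the pipeline comes from extracting the isosurface
of the *grayscale* HU field (marching cubes at the lower segmentation
threshold) rather than counting binary-mask voxels: the iso-crossing is placed
by linear interpolation inside boundary voxels, so wall excursions far below
the voxel size still move the surface.  Enclosed volume is evaluated with the
divergence theorem as a sum of signed tetrahedra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import EmptyMeshError, InvalidArgumentError, OpenMeshError, OrientationWarning
from .segmentation import LumenMask4D
from .volume import CTVolume4D


@dataclass
class SurfaceMesh:
    """Triangulated lumen surface of one cardiac phase, vertices in world mm."""

    vertices: np.ndarray       # (n, 3) mm
    faces: np.ndarray          # (m, 3) int vertex indices
    phase: int = 0
    iso: float | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise InvalidArgumentError("face references a missing vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_directed(self) -> np.ndarray:
        """All directed edges, one triple per face edge, shape (3m, 2)."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def boundary_edge_count(self) -> int:
        """Number of undirected edges not shared by exactly two faces."""
        e = np.sort(self.edges_directed(), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int((counts != 2).sum())

    def is_watertight(self) -> bool:
        return self.n_faces > 0 and self.boundary_edge_count() == 0


@dataclass
class MeshSequence:
    """One surface per cardiac phase extracted at a common iso-value."""

    meshes: list[SurfaceMesh]
    iso: float

    def __post_init__(self):
        if any(m.iso is not None and m.iso != self.iso for m in self.meshes):
            raise InvalidArgumentError("all phases must share the iso-value")

    @property
    def n_phases(self) -> int:
        return len(self.meshes)

    def __getitem__(self, p: int) -> SurfaceMesh:
        return self.meshes[p]

    def __iter__(self):
        return iter(self.meshes)


class VolumeArea(NamedTuple):
    volume: float      # mm^3
    area: float        # mm^2


def extract_isosurface(
    volume_phase: np.ndarray,
    mask_phase: np.ndarray,
    spacing,
    origin=(0.0, 0.0, 0.0),
    iso: float = 160.0,
    high: float = 890.0,
    fill_hu: float | None = None,
    phase: int = 0,
) -> SurfaceMesh:
    """Marching-cubes surface of the HU field restricted to the lumen mask.

    The mask is dilated by one voxel so the sub-voxel interface can be placed
    inside boundary voxels; voxels outside the dilated mask are set to a fill
    value below the iso level, which also closes the surface at the grid
    boundary.  HU above ``high`` (bone / calcification) are clamped to the
    fill value first, honoring the upper segmentation threshold.
    """
    hu = np.asarray(volume_phase, dtype=float)
    m = np.asarray(mask_phase, dtype=bool)
    if hu.ndim != 3 or m.shape != hu.shape:
        raise InvalidArgumentError("volume phase and mask phase must be matching 3D arrays")
    if not m.any():
        raise EmptyMeshError(f"empty mask at phase {phase}: no surface to extract")
    if fill_hu is None:
        fill_hu = min(float(hu.min()), iso - 1.0)
    field = np.where(hu > high, fill_hu, hu)
    dil = ndimage.binary_dilation(m, structure=np.ones((3, 3, 3), bool))
    field = np.where(dil, field, fill_hu)
    field = np.pad(field, 1, constant_values=fill_hu)
    if field.max() < iso:
        raise EmptyMeshError(f"no iso-crossing at {iso} HU within the mask (phase {phase})")
    verts, faces, _, _ = measure.marching_cubes(field, level=iso, spacing=tuple(spacing))
    verts = verts - np.asarray(spacing, float) + np.asarray(origin, float)  # undo padding
    mesh = SurfaceMesh(vertices=verts, faces=faces, phase=phase, iso=iso)
    return ensure_outward_orientation(mesh, warn=False)


def extract_mesh_sequence(
    volume: CTVolume4D, mask: LumenMask4D, iso: float = 160.0, high: float = 890.0
) -> MeshSequence:
    """Build the 3D+t model: one isosurface per cardiac phase."""
    meshes = [
        extract_isosurface(
            volume.phase(p), mask.phase(p), volume.spacing, volume.origin,
            iso=iso, high=high, phase=p,
        )
        for p in range(volume.n_phases)
    ]
    return MeshSequence(meshes=meshes, iso=iso)


def signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Signed enclosed volume: sum of tetrahedra (origin, v0, v1, v2)."""
    v = vertices[faces]
    return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)


def surface_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    v = vertices[faces]
    return float(np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1).sum() / 2.0)


def ensure_outward_orientation(mesh: SurfaceMesh, warn: bool = True) -> SurfaceMesh:
    """Flip all faces if the signed volume is negative (inward orientation)."""
    if mesh.n_faces and signed_volume(mesh.vertices, mesh.faces) < 0:
        if warn:
            warnings.warn("mesh was inward-oriented; faces flipped", OrientationWarning)
        return SurfaceMesh(
            vertices=mesh.vertices, faces=mesh.faces[:, ::-1],
            phase=mesh.phase, iso=mesh.iso,
        )
    return mesh


def closest_point_on_mesh(mesh: SurfaceMesh, points: np.ndarray,
                          n_candidates: int = 32) -> np.ndarray:
    """Nearest point on the triangulated surface for each query point.

    Candidate faces are prefiltered by face-centroid proximity (k nearest),
    then the exact closest point on each candidate triangle is found by
    barycentric clamping and the best is kept.  Unlike snapping to the
    nearest vertex this is continuous in the query, so transferred neck
    points do not inherit the mesh's vertex quantization.
    """
    from scipy.spatial import cKDTree

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.vertices[mesh.faces]                       # (m, 3, 3)
    centroids = tri.mean(axis=1)
    k = min(n_candidates, len(tri))
    _, cand = cKDTree(centroids).query(pts, k=k)
    cand = np.atleast_2d(cand)

    a, b, c = tri[cand, 0], tri[cand, 1], tri[cand, 2]    # (n, k, 3)
    p = pts[:, None, :]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("nkj,nkj->nk", ab, ap)
    d2 = np.einsum("nkj,nkj->nk", ac, ap)
    bp = p - b
    d3 = np.einsum("nkj,nkj->nk", ab, bp)
    d4 = np.einsum("nkj,nkj->nk", ac, bp)
    cp = p - c
    d5 = np.einsum("nkj,nkj->nk", ab, cp)
    d6 = np.einsum("nkj,nkj->nk", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(d1 / (d1 - d3), 0, 1)
        t_ac = np.clip(d2 / (d2 - d6), 0, 1)
        t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0, 1)
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom
    for arr in (t_ab, t_ac, t_bc, v_in, w_in):
        np.nan_to_num(arr, copy=False)

    close = a + ab * v_in[..., None] + ac * w_in[..., None]   # interior default
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    close = np.where(on_bc[..., None], b + (c - b) * t_bc[..., None], close)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    close = np.where(on_ac[..., None], a + ac * t_ac[..., None], close)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    close = np.where(on_ab[..., None], a + ab * t_ab[..., None], close)
    at_c = (d6 >= 0) & (d5 <= d6)
    close = np.where(at_c[..., None], c, close)
    at_b = (d3 >= 0) & (d4 <= d3)
    close = np.where(at_b[..., None], b, close)
    at_a = (d1 <= 0) & (d2 <= 0)
    close = np.where(at_a[..., None], a, close)

    best = np.argmin(np.linalg.norm(close - p, axis=2), axis=1)
    return close[np.arange(len(pts)), best]


def mesh_enclosed_volume(mesh: SurfaceMesh) -> VolumeArea:
    """Enclosed volume (mm^3) and surface area (mm^2) of a watertight mesh.

    Raises :class:`OpenMeshError` (with the boundary edge count) when the mesh
    has boundary edges; an inward-oriented mesh is corrected with a warning.
    """
    nb = mesh.boundary_edge_count()
    if mesh.n_faces == 0 or nb:
        raise OpenMeshError(nb if mesh.n_faces else -1)
    sv = signed_volume(mesh.vertices, mesh.faces)
    if sv < 0:
        warnings.warn("mesh was inward-oriented; volume sign corrected", OrientationWarning)
    return VolumeArea(volume=abs(sv), area=surface_area(mesh.vertices, mesh.faces))
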