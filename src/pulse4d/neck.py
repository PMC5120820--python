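"""Aneurysm/vessel separation on the 3D+t model.

Neck points placed on the phase-0 surface are transferred to every other
phase by rigid iterative-closest-point (ICP) registration of the surface
neighborhood around the neck, a cut surface is triangulated over the
(generally non-coplanar) transferred points, and the dome-side surface is
region-grown from a seed and capped at the cut to yield a closed mesh whose
enclosed volume is the per-phase aneurysm volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConvergenceWarning,
    FocusError,
    InvalidArgumentError,
    InvalidGeometryError,
    LeakError,
    OpenMeshError,
)
from .pulsation import VolumeCurve
from .surface import MeshSequence, SurfaceMesh, mesh_enclosed_volume, signed_volume


@dataclass
class NeckPointSet:
    """Ordered neck-delimiting points (mm) on the lumen surface of one phase."""

    points: np.ndarray      # (n, 3), n >= 3
    phase: int = 0

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 3 or self.points.shape[1] != 3:
            raise InvalidArgumentError("need >= 3 neck points with 3 coordinates each")
        if _collinear(self.points):
            raise InvalidGeometryError("neck points must not be collinear")

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def ring_radius(self) -> float:
        """Mean distance of the points from their centroid."""
        return float(np.linalg.norm(self.points - self.centroid, axis=1).mean())

    def max_surface_distance(self, mesh: SurfaceMesh) -> float:
        """Largest distance from any point to the nearest mesh vertex."""
        d, _ = cKDTree(mesh.vertices).query(self.points)
        return float(d.max())


@dataclass
class RigidTransform:
    """Rotation + translation with the ICP fit diagnostics."""

    rotation: np.ndarray       # (3, 3), orthonormal, det +1
    translation: np.ndarray    # (3,) mm
    rms: float                 # residual of the final correspondences, mm
    iterations: int
    converged: bool = True

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise InvalidArgumentError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise InvalidArgumentError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0, 0)

    @property
    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class CutSurface:
    """Centroid triangle fan over the angularly ordered neck points."""

    ordered_points: np.ndarray   # (n, 3), canonical angular order in the fit plane
    centroid: np.ndarray
    normal: np.ndarray
    phase: int = 0

    @property
    def vertices(self) -> np.ndarray:
        return np.vstack([self.ordered_points, self.centroid])

    @property
    def triangles(self) -> np.ndarray:
        n = len(self.ordered_points)
        if n == 3:                       # three points ARE the plane element
            return np.array([[0, 1, 2]], dtype=np.int64)
        return np.array([[n, i, (i + 1) % n] for i in range(n)], dtype=np.int64)

    def area(self) -> float:
        v = self.vertices[self.triangles]
        return float(np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1).sum() / 2.0)


@dataclass
class AneurysmSegmentation:
    """Dome-side closed mesh (surface + neck cap) and its volume for one phase."""

    closed_mesh: SurfaceMesh
    volume: float            # mm^3
    area: float              # mm^2
    dome_faces: np.ndarray   # indices of source-mesh faces on the dome side
    phase: int = 0
    watertight: bool = True


def _collinear(points: np.ndarray, rtol: float = 1e-9) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= rtol * max(s[0], 1e-300)


def _kabsch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form least-squares rotation + translation mapping x onto y."""
    cx, cy = x.mean(axis=0), y.mean(axis=0)
    h = (x - cx).T @ (y - cy)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, cy - r @ cx


def fit_rigid_icp(
    source_mesh: SurfaceMesh,
    target_mesh: SurfaceMesh,
    focus_center,
    focus_radius: float,
    tol: float = 1e-6,
    max_iter: int = 50,
    source_filter=None,
) -> RigidTransform:
    """Point-to-point rigid ICP of the source surface onto the target.

    Only source vertices inside the focus sphere take part (the transfer must
    track the neck, not global vasculature motion); ``source_filter`` can
    restrict them further (e.g. to the vessel side of the neck plane).
    Correspondences are nearest target vertices (ties broken toward the
    lowest vertex index); each iteration solves the orthogonal alignment in
    closed form and the loop stops when the RMS residual changes by less
    than ``tol`` mm.
    """
    if source_mesh.n_vertices == 0 or target_mesh.n_vertices == 0:
        raise InvalidArgumentError("both meshes must be non-empty")
    focus_center = np.asarray(focus_center, dtype=float).reshape(3)
    sel = np.linalg.norm(source_mesh.vertices - focus_center, axis=1) <= focus_radius
    if source_filter is not None:
        sel &= source_filter(source_mesh.vertices)
    x = source_mesh.vertices[sel]
    if len(x) < 10:
        raise FocusError(
            f"only {len(x)} source vertices inside the focus sphere (need >= 10)"
        )
    tree = cKDTree(target_mesh.vertices)
    r, t = np.eye(3), np.zeros(3)
    prev_rms = np.inf
    iters = 0
    converged = False
    for iters in range(1, max_iter + 1):
        moved = x @ r.T + t
        d, j = tree.query(moved)
        r, t = _kabsch(x, target_mesh.vertices[j])
        rms = float(np.sqrt(np.mean(np.linalg.norm(x @ r.T + t - target_mesh.vertices[j], axis=1) ** 2)))
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms
    if not converged:
        warnings.warn("ICP hit the iteration cap; returning the best transform",
                      ConvergenceWarning)
    return RigidTransform(rotation=r, translation=t, rms=rms, iterations=iters,
                          converged=converged)


def transfer_neck_points(
    points0: NeckPointSet,
    mesh_seq: MeshSequence,
    focus_radius: float | None = None,
    corrections: dict[int, NeckPointSet] | None = None,
    snap: str | None = "surface",
    dome_ref=None,
    anchor_margin: float = 1.8,
) -> tuple[list[NeckPointSet], list[RigidTransform]]:
    """Carry the phase-0 neck points to every phase via focused ICP.

    The focus sphere is centered on the neck centroid with radius defaulting
    to 1.5x the neck ring radius.  When ``dome_ref`` (a point inside the
    dome) is given, the registration anchors on the parent vessel instead:
    only focus vertices on the vessel side of the phase-0 neck plane and
    farther than ring_radius + ``anchor_margin`` (mm) from the neck centroid
    take part, and the focus reach widens to that inner radius + 3 mm.  Any
    dome surface that dips below the neck plane stays within one ring radius
    of the centroid, and the margin clears the blur reach of the imaging and
    denoising kernels, so the annulus sees only rigidly moving vessel wall;
    the dome's pulsatile deformation is not rigid and would otherwise drag
    the transferred cut along the neck normal.

    Transferred points are snapped back onto the phase-t surface so they stay
    on the 3D+t model: ``snap="surface"`` (default) projects to the nearest
    point on the triangulation, ``snap="vertex"`` to the nearest vertex, and
    ``snap=None`` leaves them where the rigid map put them.  Per-phase
    replacement points (``corrections``) mimic the manual correction step.
    """
    from .surface import closest_point_on_mesh

    corrections = corrections or {}
    source_filter = None
    if dome_ref is not None:
        # every below-plane dome point lies within one ring radius of the
        # centroid; anchor_margin adds the PSF/denoising blur reach on top
        inner = points0.ring_radius + anchor_margin
        if focus_radius is None:
            focus_radius = inner + 3.0
        cut0 = build_cut_surface(points0)
        n = cut0.normal
        if (np.asarray(dome_ref, float) - cut0.centroid) @ n < 0:
            n = -n
        c0, nn = cut0.centroid, n

        def source_filter(verts):
            # vessel side of the neck plane, outside the pulsating collar
            return ((verts - c0) @ nn <= 0.0) & (
                np.linalg.norm(verts - c0, axis=1) >= inner
            )
    if focus_radius is None:
        focus_radius = 1.5 * points0.ring_radius

    out: list[NeckPointSet] = []
    transforms: list[RigidTransform] = []
    for p in range(mesh_seq.n_phases):
        if p in corrections:
            out.append(corrections[p])
            transforms.append(RigidTransform.identity())
            continue
        if p == points0.phase:
            out.append(points0)
            transforms.append(RigidTransform.identity())
            continue
        tr = fit_rigid_icp(mesh_seq[points0.phase], mesh_seq[p],
                           points0.centroid, focus_radius,
                           source_filter=source_filter)
        pts = tr.apply(points0.points)
        if snap == "vertex":
            _, j = cKDTree(mesh_seq[p].vertices).query(pts)
            pts = mesh_seq[p].vertices[j]
        elif snap == "surface":
            pts = closest_point_on_mesh(mesh_seq[p], pts)
        elif snap is not None:
            raise InvalidArgumentError(f"unknown snap mode {snap!r}")
        out.append(NeckPointSet(points=pts, phase=p))
        transforms.append(tr)
    return out, transforms


def build_cut_surface(points: NeckPointSet, planar: bool = False) -> CutSurface:
    """Triangle fan over the neck points, ordered canonically by angle.

    Points are ordered by angle around the best-fit plane normal through
    their centroid, which makes the fan independent of input order and lets
    it pass exactly through non-coplanar points.  With ``planar`` the points
    are first projected onto the least-squares plane.
    """
    pts = points.points
    c = pts.mean(axis=0)
    centered = pts - c
    _, s, vt = np.linalg.svd(centered)
    if s[1] <= 1e-9 * max(s[0], 1e-300):
        raise InvalidGeometryError("neck points are collinear; no cut plane exists")
    n = vt[2]
    # canonical normal sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    e = np.zeros(3)
    e[int(np.argmin(np.abs(n)))] = 1.0
    u = e - (e @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    if planar:
        pts = pts - np.outer(centered @ n, n)
        centered = pts - c
    ang = np.arctan2(centered @ v, centered @ u)
    order = np.argsort(ang)
    return CutSurface(ordered_points=pts[order], centroid=pts[order].mean(axis=0),
                      normal=n, phase=points.phase)


def _segments_hit_triangles(p0: np.ndarray, p1: np.ndarray,
                            tri: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Which segments (p0->p1) intersect any triangle (Moller-Trumbore)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = (b - a)[None, :, :]
    e2 = (c - a)[None, :, :]
    d = (p1 - p0)[:, None, :]
    h = np.cross(d, e2)
    det = np.einsum("stk,stk->st", e1, h)
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = p0[:, None, :] - a[None, :, :]
    u = np.einsum("stk,stk->st", s, h) * inv
    q = np.cross(s, e1)
    v = np.einsum("stk,stk->st", d, q) * inv
    t = np.einsum("stk,stk->st", e2, q) * inv
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t >= -tol) & (t <= 1 + tol)
    return hit.any(axis=1)


def _face_edge_topology(mesh: SurfaceMesh):
    """Unique undirected edge ids per face and the face pair of each edge."""
    f = mesh.faces
    de = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    ue, inv = np.unique(np.sort(de, axis=1), axis=0, return_inverse=True)
    face_edges = inv.reshape(3, -1).T            # (m, 3) edge id per face edge
    edge_faces = -np.ones((len(ue), 2), dtype=np.int64)
    for fi in range(len(f)):
        for ei in face_edges[fi]:
            if edge_faces[ei, 0] < 0:
                edge_faces[ei, 0] = fi
            else:
                edge_faces[ei, 1] = fi
    return ue, face_edges, edge_faces


def _cap_closed_mesh(mesh: SurfaceMesh, faces_idx: np.ndarray) -> SurfaceMesh:
    """Close the sub-surface of the given faces with a centroid fan over its
    boundary edges.  Both sides of a cut share the identical cap, so their
    volumes add exactly to the whole-mesh volume."""
    sub = mesh.faces[faces_idx]
    de = np.concatenate([sub[:, [0, 1]], sub[:, [1, 2]], sub[:, [2, 0]]])
    key = np.sort(de, axis=1)
    ue, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1                   # directed edges on the rim
    rim = de[boundary]
    if len(rim) == 0:
        return SurfaceMesh(vertices=mesh.vertices, faces=sub, phase=mesh.phase, iso=mesh.iso)
    cidx = len(mesh.vertices)
    centroid = mesh.vertices[np.unique(rim)].mean(axis=0)
    cap = np.column_stack([rim[:, 1], rim[:, 0], np.full(len(rim), cidx)])
    return SurfaceMesh(
        vertices=np.vstack([mesh.vertices, centroid]),
        faces=np.vstack([sub, cap]),
        phase=mesh.phase, iso=mesh.iso,
    )


def partition_mesh(
    mesh: SurfaceMesh,
    cut: CutSurface,
    dome_seed,
    leak_fraction: float = 0.9,
    overcut: float = 1.8,
) -> AneurysmSegmentation:
    """Separate the dome from the parent vessel along the cut surface.

    Faces are region-grown from the face nearest ``dome_seed``; growth never
    crosses a mesh edge that intersects the cut fan.  For the edge-blocking
    test the fan is scaled outward about its centroid by ``overcut`` so that
    it fully severs the lumen even where the surface bulges outside the neck
    polygon between points (the knife must be wider than the vessel); the
    measured cap is still placed at the rim of the grown region.  The grown
    faces plus a centroid fan over that rim form a closed mesh whose enclosed
    volume is the aneurysm volume.  Growth reaching more than
    ``leak_fraction`` of all faces means the cut failed to separate.
    """
    dome_seed = np.asarray(dome_seed, dtype=float).reshape(3)
    if mesh.n_faces == 0:
        raise InvalidArgumentError("cannot partition an empty mesh")
    ue, face_edges, edge_faces = _face_edge_topology(mesh)

    # candidate edges near the cut; only these need intersection tests
    blade = CutSurface(
        ordered_points=cut.centroid + overcut * (cut.ordered_points - cut.centroid),
        centroid=cut.centroid, normal=cut.normal, phase=cut.phase,
    )
    tri = blade.vertices[blade.triangles]
    reach = np.linalg.norm(blade.vertices - blade.centroid, axis=1).max() * 1.5 + 1e-9
    vnear = np.linalg.norm(mesh.vertices - cut.centroid, axis=1) <= reach
    cand = vnear[ue[:, 0]] | vnear[ue[:, 1]]
    blocked = np.zeros(len(ue), dtype=bool)
    if cand.any():
        p0 = mesh.vertices[ue[cand, 0]]
        p1 = mesh.vertices[ue[cand, 1]]
        blocked[cand] = _segments_hit_triangles(p0, p1, tri)
    if not blocked.any():
        raise LeakError("cut surface does not intersect the mesh")

    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    seed_face = int(np.argmin(np.linalg.norm(centroids - dome_seed, axis=1)))
    grown = np.zeros(mesh.n_faces, dtype=bool)
    grown[seed_face] = True
    stack = [seed_face]
    while stack:
        fi = stack.pop()
        for ei in face_edges[fi]:
            if blocked[ei]:
                continue
            for fj in edge_faces[ei]:
                if fj >= 0 and not grown[fj]:
                    grown[fj] = True
                    stack.append(fj)
    frac = grown.sum() / mesh.n_faces
    if frac > leak_fraction:
        raise LeakError(
            f"region grow reached {frac:.0%} of faces; cut failed to separate the dome"
        )

    dome_faces = np.flatnonzero(grown)
    closed = _cap_closed_mesh(mesh, dome_faces)
    nb = closed.boundary_edge_count()
    if nb:
        raise OpenMeshError(nb)
    vol, area = mesh_enclosed_volume(closed)
    return AneurysmSegmentation(closed_mesh=closed, volume=vol, area=area,
                                dome_faces=dome_faces, phase=mesh.phase)


def complement_segmentation(mesh: SurfaceMesh, seg: AneurysmSegmentation) -> AneurysmSegmentation:
    """Closed mesh and volume of the vessel side (all faces not in the dome)."""
    keep = np.ones(mesh.n_faces, dtype=bool)
    keep[seg.dome_faces] = False
    closed = _cap_closed_mesh(mesh, np.flatnonzero(keep))
    nb = closed.boundary_edge_count()
    if nb:
        raise OpenMeshError(nb)
    vol, area = mesh_enclosed_volume(closed)
    return AneurysmSegmentation(closed_mesh=closed, volume=vol, area=area,
                                dome_faces=np.flatnonzero(keep), phase=mesh.phase)


@dataclass
class VolumeCurveResult:
    """Per-phase aneurysm volumes with transfer/partition diagnostics."""

    curve: VolumeCurve | None
    volumes: np.ndarray           # nan for failed phases
    icp_rms: np.ndarray
    watertight: list[bool]
    errors: dict[int, str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.errors


def aneurysm_volume_curve(
    mesh_seq: MeshSequence,
    points0: NeckPointSet,
    dome_seed,
    focus_radius: float | None = None,
    corrections: dict[int, NeckPointSet] | None = None,
    planar: bool = False,
    snap: str | None = None,
    label: str = "",
) -> VolumeCurveResult:
    """Neck transfer -> cut surface -> partition for every phase.

    The cut at phase t is the rigid image of the phase-0 neck polygon
    (``snap=None``): re-snapping the points onto each phase's surface would
    quantize the cut position (vertex snap) or drag it along with the
    inflating dome (surface snap), and either corrupts the sub-voxel volume
    differences this pipeline exists to measure.  Phases that fail are
    recorded in ``errors`` and the curve is marked incomplete; the remaining
    volumes are still returned.
    """
    point_sets, transforms = transfer_neck_points(points0, mesh_seq, focus_radius,
                                                  corrections, snap=snap,
                                                  dome_ref=dome_seed)
    n = mesh_seq.n_phases
    volumes = np.full(n, np.nan)
    watertight = [False] * n
    errors: dict[int, str] = {}
    for p in range(n):
        try:
            cut = build_cut_surface(point_sets[p], planar=planar)
            seg = partition_mesh(mesh_seq[p], cut, dome_seed)
            volumes[p] = seg.volume
            watertight[p] = seg.closed_mesh.is_watertight()
        except (LeakError, OpenMeshError, InvalidGeometryError) as exc:
            errors[p] = f"{type(exc).__name__}: {exc}"
    curve = None
    if not errors:
        curve = VolumeCurve(values=volumes, label=label)
    return VolumeCurveResult(
        curve=curve, volumes=volumes,
        icp_rms=np.array([t.rms for t in transforms]),
        watertight=watertight, errors=errors,
    )
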