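"""Synthetic pulsating-aneurysm 4D-CTA phantom with analytic ground truth.

The phantom is a saccular aneurysm (sphere) sitting on a parent vessel
(straight tube).  The *neck plane* is the plane tangent to the tube on the
aneurysm side; the aneurysm proper is the spherical dome above that plane and
the ground-truth neck ring is the circle in which the sphere crosses it.
Pulsation drives the dome volume linearly with an arterial pulse-wave
template,

    V(p) = Vmin * (1 + (A - 1) * w(p)),   w = min-max normalized template,

so the ground-truth volume ratio Vmax/Vmin equals the requested amplitude A
exactly; the sphere radius at each phase is recovered from the spherical-cap
volume equation by a bracketed root solve.

Geometry is rasterized by supersampled occupancy (default 3 samples per axis),
mapped to Hounsfield units, blurred with a Gaussian point-spread function to
emulate partial-volume gradients, and finally corrupted with i.i.d. Gaussian
noise whose SD is a fraction of the lumen attenuation (the emulated regime is
~18% of a ~400 HU lumen on a ~40 HU background, on a 0.39 x 0.39 x 0.5 mm
grid with 10 cardiac phases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .errors import InvalidArgumentError, InvalidGeometryError, OutOfBoundsError
from .pulsation import PulseWave
from .volume import CTVolume4D


def generate_pulse_template(n_phases: int, shape: str = "mca_like") -> PulseWave:
    """Analytic arterial pulse-wave stand-in sampled at ``n_phases`` points.

    The middle-cerebral-artery-like shape has a single systolic peak in the
    first 40% of the cycle, a dicrotic shoulder, and decays toward diastole;
    it is min-max normalized to [0, 1].  When measured waveform values are
    available they should be loaded from file instead (``io.load_pulse_csv``).
    """
    if n_phases < 2:
        raise InvalidArgumentError("n_phases must be >= 2")
    if shape != "mca_like":
        raise InvalidArgumentError(f"unknown template shape {shape!r}")
    t = np.arange(n_phases) / n_phases  # phase fractions of the R-R interval
    v = np.exp(-0.5 * ((t - 0.2) / 0.12) ** 2) + 0.25 * np.exp(
        -0.5 * ((t - 0.55) / 0.15) ** 2
    )
    v = (v - v.min()) / (v.max() - v.min())
    return PulseWave(values=v, source="builtin")


def spherical_cap_volume(r: float, d: float) -> float:
    """Volume of the part of a radius-``r`` sphere above a plane ``d`` below
    its center (d >= 0: more than a hemisphere)."""
    h = r + d
    return math.pi * h * h * (3.0 * r - h) / 3.0


def radius_for_cap_volume(volume: float, d: float) -> float:
    """Invert :func:`spherical_cap_volume` in ``r`` for fixed plane offset."""
    if volume <= 0:
        raise InvalidArgumentError("cap volume must be positive")
    hi = (3.0 * volume / (2.0 * math.pi)) ** (1.0 / 3.0) + d + 1e-9
    lo = max(d, 1e-12)
    return brentq(lambda r: spherical_cap_volume(r, d) - volume, lo, hi, xtol=1e-13)


@dataclass(frozen=True)
class RigidMotion:
    """Per-phase rigid transform: rotation (deg) about ``axis`` through
    ``center`` followed by ``translation`` (mm)."""

    translation: np.ndarray
    rotation_deg: float = 0.0
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def matrix(self, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Rotation matrix and net world translation: y = R x + t_net."""
        ax = np.asarray(self.axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        R = Rotation.from_rotvec(np.deg2rad(self.rotation_deg) * ax).as_matrix()
        t_net = np.asarray(center) - R @ np.asarray(center) + np.asarray(self.translation, float)
        return R, t_net


@dataclass
class PhantomSpec:
    """Full parameterization of the synthetic phantom.

    Defaults emulate the target acquisition: 0.39 x 0.39 x 0.5 mm voxels,
    10 cardiac phases, contrast-enhanced lumen ~400 HU on ~40 HU soft tissue,
    noise SD 18% of the lumen attenuation, and an 8.5 mm aneurysm dome (the
    mid-range of the 5-17 mm cohort) on a 3 mm parent vessel.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 36)
    spacing: tuple[float, float, float] = (0.39, 0.39, 0.5)
    n_phases: int = 10
    vessel_radius: float = 1.5
    vessel_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    aneurysm_center: tuple[float, float, float] | None = None
    aneurysm_base_radius: float = 4.25
    neck_offset_fraction: float = 0.5    # center sits this * base_radius above the neck plane
    lumen_hu: float = 400.0
    background_hu: float = 40.0
    noise_fraction: float = 0.18
    pulsation_amplitude: float = 1.06
    pulse_template: PulseWave | None = None
    rigid_motion: Sequence[RigidMotion] | None = None
    psf_sigma: float = 0.4               # mm
    supersampling: int = 3
    n_ring_points: int = 16
    seed: int | None = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise InvalidArgumentError("spacing must be positive")
        if self.n_phases < 2:
            raise InvalidArgumentError("n_phases must be >= 2")
        if self.pulsation_amplitude < 1.0:
            raise InvalidArgumentError("pulsation_amplitude must be >= 1")
        if not (0.0 <= self.neck_offset_fraction < 1.0):
            raise InvalidGeometryError(
                "neck plane must intersect the sphere (0 <= offset fraction < 1)"
            )
        if self.pulse_template is None:
            self.pulse_template = generate_pulse_template(self.n_phases)
        if self.pulse_template.n_phases != self.n_phases:
            raise InvalidArgumentError("pulse template length must equal n_phases")
        if self.aneurysm_center is None:
            shape = np.asarray(self.grid_shape, float)
            sp = np.asarray(self.spacing, float)
            self.aneurysm_center = tuple((shape - 1) * sp / 2.0)
        # neck existence: plane offset below the sphere center must be < radius
        if self.neck_plane_offset >= self.aneurysm_base_radius:
            raise InvalidGeometryError("aneurysm sphere and vessel tube do not intersect")
        if self.rigid_motion is not None and len(self.rigid_motion) != self.n_phases:
            raise InvalidArgumentError("rigid_motion must give one transform per phase")

    @property
    def neck_plane_offset(self) -> float:
        """Distance (mm) from sphere center down to the neck plane."""
        return self.neck_offset_fraction * self.aneurysm_base_radius

    @property
    def axis_unit(self) -> np.ndarray:
        ax = np.asarray(self.vessel_axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise InvalidArgumentError("vessel_axis must be nonzero")
        return ax / n

    @property
    def neck_normal(self) -> np.ndarray:
        """Unit normal of the neck plane: from the vessel axis toward the dome."""
        a = self.axis_unit
        z = np.array([0.0, 0.0, 1.0])
        n = z - (z @ a) * a
        if np.linalg.norm(n) < 1e-9:        # axis parallel to z: use x instead
            n = np.array([1.0, 0.0, 0.0]) - (a[0]) * a
        return n / np.linalg.norm(n)

    @property
    def vessel_point(self) -> np.ndarray:
        """A point on the vessel axis (sphere center dropped onto the axis)."""
        c = np.asarray(self.aneurysm_center, dtype=float)
        return c - self.neck_normal * (self.vessel_radius + self.neck_plane_offset)


@dataclass
class PhantomGroundTruth:
    """Analytic per-phase truth recorded at generation time."""

    volumes: np.ndarray            # (P,) dome volume, mm^3
    radii: np.ndarray              # (P,) sphere radius, mm
    neck_rings: np.ndarray         # (P, n_ring, 3) mm
    neck_ring_radius: np.ndarray   # (P,)
    transforms: list               # per-phase (R, t) world maps (identity if none)
    dome_seed: np.ndarray          # (3,) a point safely inside the dome, mm
    pulse_values: np.ndarray       # normalized template w(p)
    spec: PhantomSpec

    @property
    def amplitude(self) -> float:
        return float(self.volumes.max() / self.volumes.min())


def _subvoxel_coords(n: int, spacing: float, origin: float, ss: int) -> np.ndarray:
    """Centers of ss subsamples per voxel along one axis, shape (n*ss,)."""
    idx = np.arange(n)[:, None] + (np.arange(ss)[None, :] + 0.5) / ss - 0.5
    return origin + idx.reshape(-1) * spacing


def _occupancy_grids(spec: PhantomSpec):
    ss = spec.supersampling
    xs = _subvoxel_coords(spec.grid_shape[0], spec.spacing[0], 0.0, ss)
    ys = _subvoxel_coords(spec.grid_shape[1], spec.spacing[1], 0.0, ss)
    zs = _subvoxel_coords(spec.grid_shape[2], spec.spacing[2], 0.0, ss)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return X, Y, Z


def _fraction(inside: np.ndarray, shape, ss: int) -> np.ndarray:
    r = inside.reshape(shape[0], ss, shape[1], ss, shape[2], ss)
    return r.mean(axis=(1, 3, 5))


def rasterize_phase(
    spec: PhantomSpec,
    radius: float,
    _cache: dict | None = None,
    center=None,
    axis_point=None,
    axis_dir=None,
) -> np.ndarray:
    """Noise-free HU volume of one phase (occupancy -> HU -> PSF blur).

    ``center`` / ``axis_point`` / ``axis_dir`` override the spec geometry so
    rigid motion can be rasterized analytically (moving the object, not
    resampling the image, which would add interpolation blur).
    """
    ss = spec.supersampling
    if _cache is None:
        _cache = {}
    if "coords" not in _cache:
        _cache["coords"] = _occupancy_grids(spec)
    X, Y, Z = _cache["coords"]
    moving = axis_point is not None or axis_dir is not None
    if moving or "cyl" not in _cache:
        a = spec.axis_unit if axis_dir is None else np.asarray(axis_dir, float)
        a = a / np.linalg.norm(a)
        p0 = spec.vessel_point if axis_point is None else np.asarray(axis_point, float)
        dx, dy, dz = X - p0[0], Y - p0[1], Z - p0[2]
        dot = dx * a[0] + dy * a[1] + dz * a[2]
        r2 = (dx - dot * a[0]) ** 2 + (dy - dot * a[1]) ** 2 + (dz - dot * a[2]) ** 2
        cyl = r2 <= spec.vessel_radius ** 2
        if not moving:
            _cache["cyl"] = cyl
    else:
        cyl = _cache["cyl"]
    c = np.asarray(spec.aneurysm_center if center is None else center, float)
    sph = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius ** 2
    occ = _fraction(cyl | sph, spec.grid_shape, ss)
    hu = spec.background_hu + (spec.lumen_hu - spec.background_hu) * occ
    sigma_vox = spec.psf_sigma / np.asarray(spec.spacing)
    if spec.psf_sigma > 0:
        hu = ndimage.gaussian_filter(hu, sigma=sigma_vox, mode="nearest")
    return hu


def _neck_ring(spec: PhantomSpec, radius: float) -> tuple[np.ndarray, float]:
    d = spec.neck_plane_offset
    rho = math.sqrt(radius * radius - d * d)
    c = np.asarray(spec.aneurysm_center, float) - spec.neck_normal * d
    u = spec.axis_unit
    v = np.cross(spec.neck_normal, u)
    theta = 2 * np.pi * np.arange(spec.n_ring_points) / spec.n_ring_points
    ring = c + rho * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v))
    return ring, rho


def _assert_in_grid(spec: PhantomSpec, center: np.ndarray, radius: float) -> None:
    lo = -0.5 * np.asarray(spec.spacing)
    hi = (np.asarray(spec.grid_shape) - 0.5) * np.asarray(spec.spacing)
    if np.any(center - radius < lo) or np.any(center + radius > hi):
        raise OutOfBoundsError("rigid motion moves the aneurysm outside the grid")


def add_noise(
    noisefree: np.ndarray, noise_fraction: float, lumen_hu: float,
    seed: int | np.random.Generator | None,
) -> np.ndarray:
    """Add i.i.d. Gaussian noise of SD ``noise_fraction * lumen_hu``."""
    if noise_fraction == 0:
        return noisefree.copy()
    rng = np.random.default_rng(seed)
    return noisefree + rng.normal(0.0, noise_fraction * lumen_hu, size=noisefree.shape)


def generate_phantom_noisefree(spec: PhantomSpec) -> tuple[np.ndarray, PhantomGroundTruth]:
    """Noise-free 4D HU array plus analytic ground truth (shared by replicates)."""
    w = spec.pulse_template.values
    d = spec.neck_plane_offset
    v0 = spherical_cap_volume(spec.aneurysm_base_radius, d)
    volumes = v0 * (1.0 + (spec.pulsation_amplitude - 1.0) * w)
    radii = np.array([radius_for_cap_volume(v, d) for v in volumes])

    cache: dict = {}
    hu4 = np.empty((*spec.grid_shape, spec.n_phases))
    rings = np.empty((spec.n_phases, spec.n_ring_points, 3))
    ring_radii = np.empty(spec.n_phases)
    transforms = []
    center = np.asarray(spec.aneurysm_center, float)
    for p in range(spec.n_phases):
        ring, rho = _neck_ring(spec, radii[p])
        if spec.rigid_motion is not None:
            # rigid motion is rasterized analytically: the object moves and
            # the grid samples it (image resampling would add interpolation
            # blur that is an artifact, not part of the motion)
            mo = spec.rigid_motion[p]
            R, t = mo.matrix(center)
            moved_center = R @ center + t
            _assert_in_grid(spec, moved_center, float(radii.max()) + d)
            hu = rasterize_phase(
                spec, radii[p], cache,
                center=moved_center,
                axis_point=R @ spec.vessel_point + t,
                axis_dir=R @ spec.axis_unit,
            )
            ring = ring @ R.T + t
        else:
            hu = rasterize_phase(spec, radii[p], cache)
            R, t = np.eye(3), np.zeros(3)
        transforms.append((R, t))
        hu4[..., p] = hu
        rings[p] = ring
        ring_radii[p] = rho

    dome_seed = center + spec.neck_normal * (0.5 * spec.aneurysm_base_radius)
    if spec.rigid_motion is not None:
        R0, t0 = transforms[0]
        dome_seed = R0 @ dome_seed + t0
    truth = PhantomGroundTruth(
        volumes=volumes, radii=radii, neck_rings=rings, neck_ring_radius=ring_radii,
        transforms=transforms, dome_seed=dome_seed, pulse_values=w, spec=spec,
    )
    return hu4, truth


def generate_phantom_4d(spec: PhantomSpec) -> tuple[CTVolume4D, PhantomGroundTruth]:
    """Generate the noisy 4D phantom volume and its ground truth."""
    hu4, truth = generate_phantom_noisefree(spec)
    hu4 = add_noise(hu4, spec.noise_fraction, spec.lumen_hu, spec.seed)
    return CTVolume4D(voxels=hu4, spacing=np.asarray(spec.spacing)), truth


def apply_rigid_motion(
    volume_phase: np.ndarray,
    spacing,
    translation,
    rotation_deg: float = 0.0,
    axis=(0.0, 1.0, 0.0),
    center=None,
    origin=(0.0, 0.0, 0.0),
    check_center=None,
    check_radius: float | None = None,
) -> np.ndarray:
    """Resample one 3D phase under a rigid world map (trilinear interpolation).

    The map is y = R (x - center) + center + translation with R a rotation of
    ``rotation_deg`` about ``axis``.  If ``check_center``/``check_radius`` are
    given, the transform must keep that bounding sphere inside the grid.
    """
    volume_phase = np.asarray(volume_phase, dtype=float)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)
    t = np.asarray(translation, dtype=float).reshape(3)
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    if center is None:
        center = origin + (np.asarray(volume_phase.shape) - 1) * spacing / 2.0
    center = np.asarray(center, dtype=float).reshape(3)
    R = Rotation.from_rotvec(np.deg2rad(rotation_deg) * ax).as_matrix()

    if check_center is not None and check_radius is not None:
        moved = R @ (np.asarray(check_center, float) - center) + center + t
        lo = origin - 0.5 * spacing
        hi = origin + (np.asarray(volume_phase.shape) - 0.5) * spacing
        if np.any(moved - check_radius < lo) or np.any(moved + check_radius > hi):
            raise OutOfBoundsError("rigid motion moves the aneurysm outside the grid")

    # inverse map in index space for ndimage.affine_transform
    S = np.diag(spacing)
    Sinv = np.diag(1.0 / spacing)
    M = Sinv @ R.T @ S
    offset = Sinv @ (R.T @ (origin - center - t) + center - origin)
    return ndimage.affine_transform(
        volume_phase, M, offset=offset, order=1, mode="nearest"
    )
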