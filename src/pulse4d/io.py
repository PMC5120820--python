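"""File I/O: 4D NIfTI volumes, neck/pulse/curve CSVs, JSON reports, meshes.

NIfTI is the reference volume format (single file, spacing in the header)
with the cardiac phase as the 4th dimension.  All CSVs are comma-delimited
with a '.' decimal and a header row; lines starting with '#' are comments
(used to embed the pipeline configuration hash).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .phantom import PhantomGroundTruth
from .pulsation import PulseWave, VolumeCurve
from .segmentation import LumenMask4D
from .surface import SurfaceMesh
from .volume import CTVolume4D

#: fixed column order of the volume-curve CSV (regression-test stable)
CURVE_COLUMNS = ["phase", "volume_mm3", "icp_rms", "watertight"]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(np.asarray(spacing, float))
    aff[:3, 3] = np.asarray(origin, float)
    return aff


def write_volume_4d(volume: CTVolume4D, path, description: str = "") -> None:
    img = nib.Nifti1Image(volume.voxels.astype(np.float64),
                          _affine(volume.spacing, volume.origin))
    img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_volume_4d(path) -> CTVolume4D:
    """Load a 4D (x, y, z, phase) NIfTI; 3D files are a dimension error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise InvalidArgumentError(
            f"expected a 4D (x, y, z, phase) NIfTI, got {data.ndim}D; "
            "use read_phase_files for one 3D file per phase"
        )
    spacing = np.asarray(img.header.get_zooms()[:3], float)
    origin = np.asarray(img.affine[:3, 3], float)
    return CTVolume4D(voxels=data.astype(float), spacing=spacing, origin=origin)


def read_phase_files(paths) -> CTVolume4D:
    """Stack one 3D NIfTI per cardiac phase into a 4D volume."""
    paths = [Path(p) for p in paths]
    if len(paths) < 2:
        raise InvalidArgumentError("need at least 2 phase files")
    imgs = [nib.load(str(p)) for p in paths]
    data = np.stack([np.asanyarray(i.dataobj) for i in imgs], axis=-1)
    if data.ndim != 4:
        raise InvalidArgumentError("phase files must each be 3D")
    spacing = np.asarray(imgs[0].header.get_zooms()[:3], float)
    origin = np.asarray(imgs[0].affine[:3, 3], float)
    return CTVolume4D(voxels=data.astype(float), spacing=spacing, origin=origin)


def write_mask_4d(mask: LumenMask4D, path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8),
                          _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))


def read_mask_4d(path, low: float = 160.0, high: float = 890.0) -> LumenMask4D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(bool)
    if data.ndim != 4:
        raise InvalidArgumentError("mask NIfTI must be 4D")
    return LumenMask4D(mask=data, low=low, high=high,
                       spacing=np.asarray(img.header.get_zooms()[:3], float),
                       origin=np.asarray(img.affine[:3, 3], float))


def load_pulse_csv(path) -> PulseWave:
    """Load a pulse-wave template (one value per row or a 'value' column) and
    min-max normalize it, preserving order."""
    df = pd.read_csv(path, comment="#")
    col = "value" if "value" in df.columns else df.columns[-1]
    v = df[col].to_numpy(dtype=float)
    if v.size < 2:
        raise InvalidArgumentError("pulse template needs >= 2 samples")
    rng = v.max() - v.min()
    if rng == 0:
        raise InvalidArgumentError("pulse template is constant")
    return PulseWave(values=(v - v.min()) / rng, source=str(path))


def save_pulse_csv(pulse: PulseWave, path) -> None:
    pd.DataFrame({"phase": np.arange(pulse.n_phases),
                  "value": pulse.values}).to_csv(path, index=False)


def load_neck_csv(path):
    """Neck points / dome seed CSV: columns x,y,z in mm, one point per row."""
    df = pd.read_csv(path, comment="#")
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(cols) == 3:
        return df[cols].to_numpy(dtype=float)
    return df.iloc[:, :3].to_numpy(dtype=float)


def save_neck_csv(points: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(points, float), columns=["x", "y", "z"]).to_csv(path, index=False)


def load_volume_table_csv(path, phase_column: str = "phase") -> list[VolumeCurve]:
    """Load a wide per-aneurysm volume table: rows = cardiac phases, one
    column per aneurysm (a leading phase column is ignored).  This is the
    layout of a measured-volumes supplementary table exported to CSV."""
    df = pd.read_csv(path, comment="#")
    cols = [c for c in df.columns if c != phase_column]
    if not cols:
        raise InvalidArgumentError("no curve columns in volume table")
    return [VolumeCurve(values=df[c].to_numpy(dtype=float), label=str(c)) for c in cols]


def write_curve_csv(path, volumes, icp_rms, watertight, config_hash: str | None = None) -> None:
    """Volume-curve CSV with the fixed column order phase, volume_mm3,
    icp_rms, watertight; the config hash goes into a leading comment."""
    n = len(volumes)
    df = pd.DataFrame({
        "phase": np.arange(n),
        "volume_mm3": np.asarray(volumes, float),
        "icp_rms": np.asarray(icp_rms, float),
        "watertight": [bool(w) for w in watertight],
    })[CURVE_COLUMNS]
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_curve_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path, config_hash: str | None = None) -> None:
    out = dict(obj)
    if config_hash:
        out["config_hash"] = config_hash
    Path(path).write_text(json.dumps(out, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating, np.bool_)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_ground_truth(truth: PhantomGroundTruth, json_path, csv_path=None,
                       config_hash: str | None = None) -> None:
    """Phantom ground truth as JSON (full) + CSV (per-phase volumes)."""
    write_json({
        "volumes_mm3": truth.volumes,
        "radii_mm": truth.radii,
        "neck_ring_radius_mm": truth.neck_ring_radius,
        "neck_rings_mm": truth.neck_rings,
        "dome_seed_mm": truth.dome_seed,
        "pulse_values": truth.pulse_values,
        "amplitude": truth.amplitude,
        "transforms": [{"rotation": r, "translation": t} for r, t in truth.transforms],
    }, json_path, config_hash)
    if csv_path is not None:
        pd.DataFrame({
            "phase": np.arange(len(truth.volumes)),
            "true_volume_mm3": truth.volumes,
        }).to_csv(csv_path, index=False)


def export_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a surface as STL or PLY (by file extension) via trimesh."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))
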