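"""Standard-format I/O: NIfTI volumes, CSV landmarks/samples, VTK meshes, JSON.

Volumes round-trip through nibabel with their affine; meshes are written as
legacy-ASCII VTK POLYDATA with per-vertex point-data arrays so they open
directly in ParaView-class viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import IntensityVolume, LabelVolume
from .reconstruction import FatVolumeModel, SurfaceMesh
from .registration import LandmarkSet, RigidTransform


# ---------------------------------------------------------------- volumes

def read_volume(path: str | Path) -> LabelVolume | IntensityVolume:
    """Load a NIfTI volume; integer dtype dispatches to LabelVolume,
    floating dtype to IntensityVolume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D in {path}")
    affine = np.asarray(img.affine, dtype=float)
    if np.issubdtype(data.dtype, np.integer):
        return LabelVolume(data, affine)
    return IntensityVolume(data.astype(np.float64), affine)


def write_volume(vol: LabelVolume | IntensityVolume, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data, vol.affine)
    nib.save(img, str(path))


# -------------------------------------------------------------- landmarks

def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(landmarks.coords, columns=["x", "y", "z"])
    df.insert(0, "name", landmarks.names)
    df.to_csv(path, index=False)


def read_landmarks(path: str | Path) -> LandmarkSet:
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    return LandmarkSet(list(df["name"]), df[["x", "y", "z"]].to_numpy(dtype=float))


# -------------------------------------------------------------- transforms

def write_transform(t: RigidTransform, path: str | Path, rms_mm: float | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "rotation_row_major": t.rotation.reshape(-1).tolist(),
        "translation_mm": t.translation.tolist(),
    }
    if rms_mm is not None:
        payload["rms_mm"] = rms_mm
    path.write_text(json.dumps(payload, indent=2))


def read_transform(path: str | Path) -> RigidTransform:
    payload = json.loads(Path(path).read_text())
    return RigidTransform(
        np.asarray(payload["rotation_row_major"], dtype=float).reshape(3, 3),
        np.asarray(payload["translation_mm"], dtype=float),
    )


# ------------------------------------------------------------------ meshes

def write_vtk_polydata(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a triangulated surface as legacy-ASCII VTK POLYDATA with the
    mesh's per-vertex attributes as point-data scalar arrays."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines: list[str] = [
        "# vtk DataFile Version 3.0",
        "fibrofat surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} float",
    ]
    lines += [" ".join(f"{c:.6f}" for c in v) for v in mesh.vertices]
    m = len(mesh.triangles)
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in mesh.triangles]
    if mesh.vertex_attrs:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in mesh.vertex_attrs.items():
            dtype = "int" if np.issubdtype(np.asarray(arr).dtype, np.integer) else "float"
            lines.append(f"SCALARS {name} {dtype} 1")
            lines.append("LOOKUP_TABLE default")
            if dtype == "int":
                lines += [str(int(v)) for v in arr]
            else:
                lines += [f"{float(v):.6f}" for v in arr]
    path.write_text("\n".join(lines) + "\n")


def write_fat_model(fat: FatVolumeModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(fat.points, columns=["x", "y", "z"])
    df["volume_mm3"] = fat.volumes
    df.to_csv(path, index=False)


def read_fat_model(path: str | Path) -> FatVolumeModel:
    df = pd.read_csv(path)
    return FatVolumeModel(
        df[["x", "y", "z"]].to_numpy(dtype=float),
        df["volume_mm3"].to_numpy(dtype=float),
    )
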