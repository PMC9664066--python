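"""Geometric reconstruction: label volumes -> surfaces and volumetric fat samples.

Two objects feed the spatial analysis: a triangulated LA surface (marching
cubes on the binary blood-pool field, iso-level 0.5, vertices in world mm) and
a volumetric representation of the fat as volume-weighted sample points. Fat
voxels are subdivided so the sample spacing does not exceed a target (1 mm by
default, matching the working resolution of the distance/volume metrics);
subdivision conserves total volume exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import measure


@dataclass
class SurfaceMesh:
    """Triangulated surface in world mm with named per-vertex attributes."""

    vertices: np.ndarray  # (N, 3) world mm
    triangles: np.ndarray  # (M, 3) vertex indices
    vertex_attrs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")
        for name, arr in self.vertex_attrs.items():
            if len(arr) != len(self.vertices):
                raise ValueError(f"attribute {name!r} length != vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def _trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    @property
    def area_mm2(self) -> float:
        return float(self._trimesh().area)

    @property
    def enclosed_volume_mm3(self) -> float:
        """Signed volume by the divergence theorem (positive for a closed,
        outward-oriented surface)."""
        return float(abs(self._trimesh().volume))

    def with_attr(self, name: str, values: np.ndarray) -> "SurfaceMesh":
        attrs = dict(self.vertex_attrs)
        attrs[name] = np.asarray(values)
        return SurfaceMesh(self.vertices, self.triangles, attrs)


@dataclass
class FatVolumeModel:
    """Volume-weighted fat sample points; the weights sum to the total EAT volume."""

    points: np.ndarray  # (K, 3) world mm
    volumes: np.ndarray  # (K,) mm^3

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.volumes = np.asarray(self.volumes, dtype=float).reshape(-1)
        if len(self.points) != len(self.volumes):
            raise ValueError("points and volumes length mismatch")
        if np.any(self.volumes <= 0):
            raise ValueError("all sample volumes must be > 0")

    @property
    def n_samples(self) -> int:
        return len(self.points)

    @property
    def total_volume_mm3(self) -> float:
        return float(self.volumes.sum())


def extract_surface(
    mask: np.ndarray,
    spacing,
    origin=(0.0, 0.0, 0.0),
    smoothing_iterations: int = 10,
) -> SurfaceMesh:
    """Iso-surface of a binary field at level 0.5, vertices in world mm.

    The raw marching-cubes surface of a binary field carries a staircase area
    bias of roughly +9-10% regardless of resolution, so the mesh is relaxed
    with shrink-compensated Taubin smoothing (volume-preserving; 10 iterations
    by default, set ``smoothing_iterations=0`` for the raw surface). The mask
    must not touch the grid boundary (the iso-surface would be clipped open);
    pad the volume first if it does.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if not mask.any():
        raise ValueError("cannot extract a surface from an empty mask")
    for axis in range(3):
        first = np.take(mask, 0, axis=axis)
        last = np.take(mask, -1, axis=axis)
        if first.any() or last.any():
            raise ValueError(
                f"mask touches the grid boundary on axis {axis}; pad the volume "
                "before surface extraction"
            )
    verts, faces, _, _ = measure.marching_cubes(
        mask.astype(np.float32), level=0.5, spacing=tuple(spacing)
    )
    if smoothing_iterations > 0:
        tm = trimesh.Trimesh(verts, faces, process=False)
        trimesh.smoothing.filter_taubin(
            tm, lamb=0.5, nu=0.53, iterations=smoothing_iterations
        )
        verts = np.asarray(tm.vertices)
        faces = np.asarray(tm.faces)
    verts = verts + np.asarray(origin, dtype=float)
    return SurfaceMesh(vertices=verts, triangles=faces)


def volumetrize_fat(
    fat_mask: np.ndarray,
    spacing,
    target_spacing_mm: float = 1.0,
    origin=(0.0, 0.0, 0.0),
) -> FatVolumeModel:
    """Turn a binary fat mask into volume-weighted sample points.

    Each voxel is split into ceil(spacing_i / target) sub-cells per axis so that
    sample spacing <= target_spacing_mm; every sample sits at a sub-cell centre
    and carries the sub-cell volume. Total volume equals voxel count x voxel
    volume by construction. An empty mask yields an empty (valid) model.
    """
    fat_mask = np.asarray(fat_mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if target_spacing_mm <= 0:
        raise ValueError("target_spacing_mm must be > 0")
    idx = np.argwhere(fat_mask)
    if len(idx) == 0:
        return FatVolumeModel(np.empty((0, 3)), np.empty((0,)))
    factors = np.maximum(1, np.ceil(spacing / target_spacing_mm).astype(int))
    sub = spacing / factors
    # sub-cell centre offsets relative to the voxel centre
    offsets = np.stack(
        np.meshgrid(
            *(((np.arange(f) + 0.5) * s - sp / 2.0) for f, s, sp in zip(factors, sub, spacing)),
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    centers = idx * spacing + origin
    points = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    vol_per_sample = float(np.prod(spacing)) / len(offsets)
    volumes = np.full(len(points), vol_per_sample)
    return FatVolumeModel(points=points, volumes=volumes)


def map_fibrosis_to_surface(
    mesh: SurfaceMesh,
    fibrotic_mask: np.ndarray,
    wall_mask: np.ndarray,
    spacing,
    max_assign_mm: float = 3.0,
    origin=(0.0, 0.0, 0.0),
) -> SurfaceMesh:
    """Transfer the wall's fibrotic/non-fibrotic labels onto surface vertices.

    Each vertex inherits the label of the nearest wall-voxel centroid
    (deterministic; exact distance ties resolved to the lowest linear voxel
    index). Vertices farther than ``max_assign_mm`` from any wall voxel are
    labeled non-fibrotic and counted in a warning.
    """
    wall_mask = np.asarray(wall_mask, dtype=bool)
    fibrotic_mask = np.asarray(fibrotic_mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if not wall_mask.any():
        raise ValueError("wall mask is empty; cannot map fibrosis to surface")
    idx = np.argwhere(wall_mask)  # argwhere is ordered by linear index
    centers = idx * spacing + np.asarray(origin, dtype=float)
    labels = fibrotic_mask[tuple(idx.T)]
    tree = cKDTree(centers)
    dist, nearest = tree.query(mesh.vertices, k=1)
    # enforce lowest-linear-index tie-break among exactly equidistant voxels
    fib = labels[nearest].copy()
    tie_check = tree.query_ball_point(mesh.vertices, dist * (1 + 1e-12) + 1e-12)
    for v, cand in enumerate(tie_check):
        if len(cand) > 1:
            d2 = np.sum((centers[cand] - mesh.vertices[v]) ** 2, axis=1)
            best = np.min(d2)
            winners = [c for c, dd in zip(cand, d2) if dd == best]
            fib[v] = labels[min(winners)]
    unassigned = dist > max_assign_mm
    if unassigned.any():
        warnings.warn(
            f"{int(unassigned.sum())} surface vertices farther than "
            f"{max_assign_mm} mm from any wall voxel; labeled non-fibrotic",
            stacklevel=2,
        )
        fib[unassigned] = False
    return mesh.with_attr("fibrotic", fib.astype(np.uint8))
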