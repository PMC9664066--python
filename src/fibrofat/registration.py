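"""Landmark-based rigid alignment between acquisition frames.

The fat (Dixon-type) and fibrosis (LGE-type) volumes live in different world
frames related, to good approximation, by a rigid transform. Alignment uses
corresponding anatomical landmarks (pulmonary-vein ostia, mitral annulus, LA
appendage analogs) and the closed-form least-squares solution (Kabsch/Umeyama
via SVD of the cross-covariance, with reflection correction). No scaling or
shear: translation and rotation only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class LandmarkSet:
    """Named corresponding points in world mm."""

    names: list[str]
    coords: np.ndarray  # (L, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.names = list(self.names)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("landmark coords must have shape (L, 3)")
        if len(self.names) != len(self.coords):
            raise ValueError("names and coords length mismatch")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class RigidTransform:
    """x -> R x + t with R a proper rotation (det +1, no scale/shear)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation length 3")
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (max |R'R - I| = {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has det -1 (reflection); not a rigid motion")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler_deg(
        cls, angles_deg: tuple[float, float, float], translation: tuple[float, float, float]
    ) -> "RigidTransform":
        """Intrinsic x-y-z rotations by the given angles (degrees), then translate."""
        ax, ay, az = np.deg2rad(angles_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return cls(rz @ ry @ rx, np.asarray(translation, dtype=float))

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return self ∘ inner (apply ``inner`` first)."""
        return RigidTransform(
            self.rotation @ inner.rotation,
            self.rotation @ inner.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


def fit_rigid(moving: LandmarkSet, fixed: LandmarkSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping ``moving`` landmarks onto ``fixed``.

    Landmarks correspond by name and order (checked). Returns the transform and
    the post-fit RMS residual in mm. Requires >= 3 non-collinear points for a
    unique rotation.
    """
    if moving.names != fixed.names:
        raise ValueError(
            f"landmark name mismatch: {moving.names} vs {fixed.names}"
        )
    if len(moving) < 3:
        raise ValueError("at least 3 landmarks are required for a rigid fit")
    a = moving.coords
    b = fixed.coords
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    # collinearity check: centred points must span at least a plane
    if np.linalg.matrix_rank(a0, tol=1e-9 * max(1.0, np.abs(a0).max())) < 2:
        raise ValueError("landmarks are collinear; rotation is not identifiable")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - rot @ ca
    transform = RigidTransform(rot, t)
    resid = transform.apply_points(a) - b
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rms


def apply_rigid(transform: RigidTransform, obj):
    """Apply a rigid transform to a LandmarkSet, SurfaceMesh or FatVolumeModel.

    Coordinates map x -> R x + t; per-vertex attributes and volume weights are
    carried over unchanged (a rigid motion preserves volumes).
    """
    from .reconstruction import FatVolumeModel, SurfaceMesh  # local import: avoid cycle

    if isinstance(obj, LandmarkSet):
        return LandmarkSet(list(obj.names), transform.apply_points(obj.coords))
    if isinstance(obj, SurfaceMesh):
        return replace(
            obj,
            vertices=transform.apply_points(obj.vertices),
            triangles=obj.triangles.copy(),
            vertex_attrs={k: v.copy() for k, v in obj.vertex_attrs.items()},
        )
    if isinstance(obj, FatVolumeModel):
        return FatVolumeModel(
            points=transform.apply_points(obj.points),
            volumes=obj.volumes.copy(),
        )
    raise TypeError(f"cannot apply rigid transform to {type(obj).__name__}")
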