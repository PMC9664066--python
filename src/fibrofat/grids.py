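"""Voxel-grid containers for labeled and intensity volumes.

All geometry in this package is metric: voxel indices are mapped to world
millimetres through an axis-aligned affine (``world = index * spacing +
origin``, with the voxel *centre* at the mapped point). Downstream modules
(surface extraction, distance fields, volume queries) operate exclusively in
world mm, never in raw index units, because the quantities of interest are
metric (2 mm wall thickness, 5 mm query radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Tissue(IntEnum):
    """Label classes used by the phantom and the pipeline."""

    BACKGROUND = 0
    BLOOD_POOL = 1
    WALL = 2
    EAT = 3          # atrial epicardial fat
    PERICARDIUM = 4
    VENTRICULAR_EAT = 5


def make_affine(spacing: np.ndarray, origin: np.ndarray | None = None) -> np.ndarray:
    """Axis-aligned affine mapping voxel index -> world mm (voxel centre)."""
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive lengths, got {spacing!r}")
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    if origin is not None:
        aff[:3, 3] = np.asarray(origin, dtype=float)
    return aff


def _check_affine(affine: np.ndarray) -> None:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    offdiag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    if np.any(offdiag != 0):
        raise ValueError("only axis-aligned (diagonal) affines are supported")
    if np.any(np.diag(affine[:3, :3]) <= 0):
        raise ValueError("affine must have positive voxel spacings")


@dataclass
class _Volume:
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm."""
        return np.diag(self.affine[:3, :3]).copy()

    @property
    def origin(self) -> np.ndarray:
        """World coordinate of the centre of voxel (0, 0, 0), mm."""
        return self.affine[:3, 3].copy()

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World-mm centres of all voxels (or of ``mask`` voxels), shape (K, 3)."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(np.asarray(mask))
        return idx * self.spacing + self.origin

    def same_grid(self, other: "_Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def require_same_grid(self, other: "_Volume", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"grid mismatch between {what}: shapes {self.shape} vs {other.shape}, "
                "or affines differ"
            )


@dataclass
class LabelVolume(_Volume):
    """Integer label map (tissue classes) on a metric grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError("LabelVolume requires an integer-typed array")

    def mask(self, label: int | Tissue) -> np.ndarray:
        return self.data == int(label)


@dataclass
class IntensityVolume(_Volume):
    """Floating-point signal volume (e.g. LGE) on a metric grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
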