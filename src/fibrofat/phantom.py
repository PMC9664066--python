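"""Synthetic LA / fat / fibrosis phantom generator.

Patient MRI is replaced by a controllable digital phantom: an ellipsoidal LA
blood pool with a thin wall (built by metric dilation, like the analysis
pipeline's own wall construction), a pericardial shell at a fixed outward gap,
spherical fat depots confined to the layer between wall and pericardium, a
separately labeled ventricular-fat slab, angular-cap fibrotic wall patches
with elevated synthetic LGE signal, and two acquisition frames related by a
known rigid transform (landmark analogs are provided in both frames).

The key experimental dial is ``coloc_mode``: fat depots are planted inside the
fibrotic caps (``near``), away from every cap (``far``), or uniformly
(``random``), giving cohorts with known ground-truth colocalization direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import IntensityVolume, LabelVolume, Tissue, make_affine
from .registration import LandmarkSet, RigidTransform
from .segmentation import build_wall_mask

_LANDMARK_DIRECTIONS = {
    # unit directions (in ellipsoid-normalised coordinates) of the anatomical
    # landmark analogs: two pulmonary-vein ostia, mitral annulus, appendage
    "RSPV": np.array([0.30, 0.55, 0.78]),
    "LIPV": np.array([-0.55, 0.50, 0.67]),
    "MV": np.array([0.0, -0.20, -0.98]),
    "LAA": np.array([0.90, -0.30, 0.32]),
}


@dataclass
class PhantomConfig:
    """Geometry, signal and experiment parameters for one synthetic case."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    la_semiaxes_mm: tuple[float, float, float] = (24.0, 20.0, 18.0)
    wall_thickness_mm: float = 2.0
    pericardium_offset_mm: float = 6.0
    pericardium_thickness_mm: float = 1.5
    n_fat_depots: int = 10
    fat_depot_radius_mm: float = 6.0
    fat_offset_mm: float = 3.0
    fibrosis_fraction: float = 0.17
    fibrosis_patch_count: int = 3
    lge_baseline_mean: float = 40.0
    lge_baseline_sd: float = 5.0
    lge_fibrosis_delta: float = 30.0
    coloc_mode: str = "random"  # near | far | random
    ventricular_fat_slab_mm: float = 8.0
    rigid_misalignment_deg: tuple[float, float, float] = (5.0, -3.0, 8.0)
    rigid_misalignment_mm: tuple[float, float, float] = (4.0, -2.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = {
            "voxel_size_mm": self.voxel_size_mm,
            "la_semiaxes_mm": self.la_semiaxes_mm,
        }
        for name, vals in lengths.items():
            if np.any(np.asarray(vals) <= 0):
                raise ValueError(f"{name} must be positive, got {vals}")
        for name in ("wall_thickness_mm", "pericardium_offset_mm",
                     "pericardium_thickness_mm", "fat_depot_radius_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise ValueError("fibrosis_fraction must lie in [0, 1]")
        if self.coloc_mode not in ("near", "far", "random"):
            raise ValueError(f"coloc_mode must be near|far|random, got {self.coloc_mode!r}")
        if self.fibrosis_fraction > 0 and self.fibrosis_patch_count < 1:
            raise ValueError(
                "fibrosis_fraction > 0 is unreachable with fibrosis_patch_count = 0"
            )
        if self.n_fat_depots < 0:
            raise ValueError("n_fat_depots must be >= 0")


@dataclass
class PhantomTruth:
    """Ground-truth record stored with every generated case."""

    fibrosis_fraction: float
    cap_directions: np.ndarray  # (P, 3) unit vectors, normalised coords
    cap_angular_radius_rad: float
    depot_centers: np.ndarray  # (D, 3) world mm, canonical (LGE) frame
    coloc_mode: str
    transform_lge_to_dixon: RigidTransform
    seed: int


@dataclass
class PhantomCase:
    labels: LabelVolume
    lge: IntensityVolume
    landmarks_lge: LandmarkSet
    landmarks_dixon: LandmarkSet
    truth: PhantomTruth
    config: PhantomConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _ellipsoid_level(centers: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    w = (centers - center) / semiaxes
    return np.sum(w * w, axis=-1)


def _voxel_center_grid(shape, spacing) -> np.ndarray:
    idx = np.indices(shape).astype(float)
    return np.stack([idx[i] * spacing[i] for i in range(3)], axis=-1)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sample_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _sample_direction_in_cap(rng, cap_dir: np.ndarray, max_angle: float) -> np.ndarray:
    """Uniform direction within an angular cap around ``cap_dir``."""
    cos_max = np.cos(max_angle)
    z = rng.uniform(cos_max, 1.0)
    phi = rng.uniform(0.0, 2 * np.pi)
    s = np.sqrt(1 - z * z)
    local = np.array([s * np.cos(phi), s * np.sin(phi), z])
    # rotate local +z onto cap_dir
    zaxis = np.array([0.0, 0.0, 1.0])
    if np.allclose(cap_dir, zaxis):
        return local
    if np.allclose(cap_dir, -zaxis):
        return -local
    axis = _unit(np.cross(zaxis, cap_dir))
    angle = np.arccos(np.clip(cap_dir @ zaxis, -1, 1))
    k = axis
    return (local * np.cos(angle)
            + np.cross(k, local) * np.sin(angle)
            + k * (k @ local) * (1 - np.cos(angle)))


def _fibrotic_cap_mask(
    wall_mask: np.ndarray,
    centers: np.ndarray,
    la_center: np.ndarray,
    semiaxes: np.ndarray,
    cap_dirs: np.ndarray,
    target_fraction: float,
) -> tuple[np.ndarray, float]:
    """Select wall voxels inside angular caps; cap radius solved by bisection
    so the achieved fibrotic fraction matches the target."""
    wall_idx = np.argwhere(wall_mask)
    w = (centers[tuple(wall_idx.T)] - la_center) / semiaxes
    dirs = w / np.linalg.norm(w, axis=1, keepdims=True)
    # angle to the closest cap centre
    cosines = dirs @ cap_dirs.T
    min_angle = np.arccos(np.clip(cosines.max(axis=1), -1, 1))

    if target_fraction == 0.0:
        return np.zeros_like(wall_mask), 0.0
    lo, hi = 0.0, np.pi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        frac = float(np.mean(min_angle <= mid))
        if frac < target_fraction:
            lo = mid
        else:
            hi = mid
    theta = hi
    sel = min_angle <= theta
    fib = np.zeros_like(wall_mask)
    fib[tuple(wall_idx[sel].T)] = True
    return fib, float(theta)


def make_la_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate one synthetic case (labels, LGE signal, landmarks, truth).

    Deterministic: identical config (including seed) gives bit-identical
    arrays. Raises a sizing error if the pericardial shell would not fit in
    the grid with a 2-voxel margin.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    spacing = np.asarray(config.voxel_size_mm, dtype=float)
    semiaxes = np.asarray(config.la_semiaxes_mm, dtype=float)
    extent = np.asarray(shape) * spacing
    la_center = extent / 2.0

    outer_reach = semiaxes + (config.wall_thickness_mm + config.pericardium_offset_mm
                              + config.pericardium_thickness_mm)
    margin = 2 * spacing
    if np.any(la_center - outer_reach < margin) or np.any(la_center + outer_reach > extent - margin):
        raise ValueError(
            "grid too small: pericardial shell (reach "
            f"{outer_reach} mm) does not fit within the grid extent {extent} mm "
            "with a 2-voxel margin"
        )

    centers = _voxel_center_grid(shape, spacing)
    lvl_pool = _ellipsoid_level(centers, la_center, semiaxes)
    pool = lvl_pool <= 1.0

    # wall by the same metric dilation the analysis pipeline applies
    wall = build_wall_mask(pool, spacing, config.wall_thickness_mm).wall_mask

    s_wall_out = semiaxes + config.wall_thickness_mm
    s_peri_in = s_wall_out + config.pericardium_offset_mm
    s_peri_out = s_peri_in + config.pericardium_thickness_mm
    lvl_wall_out = _ellipsoid_level(centers, la_center, s_wall_out)
    lvl_peri_in = _ellipsoid_level(centers, la_center, s_peri_in)
    lvl_peri_out = _ellipsoid_level(centers, la_center, s_peri_out)
    pericardium = (lvl_peri_in > 1.0) & (lvl_peri_out <= 1.0)

    # fibrotic caps on the wall
    if config.fibrosis_patch_count > 0:
        cap_dirs = np.stack([_sample_direction(rng) for _ in range(config.fibrosis_patch_count)])
    else:
        cap_dirs = np.zeros((0, 3))
    if config.fibrosis_fraction > 0:
        fibrotic, theta = _fibrotic_cap_mask(
            wall, centers, la_center, semiaxes, cap_dirs, config.fibrosis_fraction
        )
    else:
        fibrotic, theta = np.zeros_like(wall), 0.0
    achieved = float(fibrotic.sum()) / float(wall.sum())
    if config.fibrosis_fraction > 0 and abs(achieved - config.fibrosis_fraction) > 0.03:
        raise ValueError(
            f"achieved fibrosis fraction {achieved:.3f} deviates more than 0.03 "
            f"from the requested {config.fibrosis_fraction:.3f}; the requested "
            f"fraction is unreachable with patch_count={config.fibrosis_patch_count}"
        )

    # fat depot centres on the mid-gap ellipsoid, direction per coloc_mode
    depot_dirs = []
    for _ in range(config.n_fat_depots):
        if config.coloc_mode == "near" and len(cap_dirs):
            cap = cap_dirs[rng.integers(len(cap_dirs))]
            depot_dirs.append(_sample_direction_in_cap(rng, cap, max(theta * 0.8, 0.05)))
        elif config.coloc_mode == "far" and len(cap_dirs):
            for _try in range(10_000):
                d = _sample_direction(rng)
                ang = np.arccos(np.clip(cap_dirs @ d, -1, 1))
                if np.all(ang > theta + 0.35):  # keep depots clear of every cap
                    depot_dirs.append(d)
                    break
            else:
                raise ValueError(
                    "could not place a fat depot away from the fibrotic caps; "
                    "reduce fibrosis_fraction or patch count"
                )
        else:
            depot_dirs.append(_sample_direction(rng))
    s_depot = s_wall_out + config.fat_offset_mm
    depot_centers = np.array(
        [la_center + s_depot * d for d in depot_dirs]
    ).reshape(-1, 3)

    between = (lvl_wall_out > 1.0) & (lvl_peri_in <= 1.0) & ~pericardium
    eat = np.zeros(shape, dtype=bool)
    r2 = config.fat_depot_radius_mm**2
    for c in depot_centers:
        eat |= np.sum((centers - c) ** 2, axis=-1) <= r2
    # strictly between wall exterior and pericardium: also exclude the
    # discretised wall itself (metric dilation can reach past the level set)
    eat &= between & ~wall & ~pool

    # ventricular-fat analog: slab near the bottom of the grid, clear of the
    # atrial structures, enabling the total-vs-LA fat distinction
    vent = np.zeros(shape, dtype=bool)
    if config.ventricular_fat_slab_mm > 0:
        z_centers = centers[..., 2]
        z_lo = 2 * spacing[2]
        z_hi = z_lo + config.ventricular_fat_slab_mm
        lateral = np.sum(((centers[..., :2] - la_center[:2]) / semiaxes[:2]) ** 2, axis=-1) <= 1.0
        vent = (z_centers >= z_lo) & (z_centers <= z_hi) & lateral
        vent &= ~(pool | wall | pericardium | eat)

    labels = np.zeros(shape, dtype=np.int16)
    labels[pool] = Tissue.BLOOD_POOL
    labels[wall] = Tissue.WALL
    labels[eat] = Tissue.EAT
    labels[pericardium] = Tissue.PERICARDIUM
    labels[vent] = Tissue.VENTRICULAR_EAT

    lge = rng.normal(config.lge_baseline_mean, config.lge_baseline_sd, size=shape)
    lge[fibrotic] += config.lge_fibrosis_delta

    lm_names = list(_LANDMARK_DIRECTIONS)
    lm_coords = np.array(
        [la_center + semiaxes * _unit(_LANDMARK_DIRECTIONS[n]) for n in lm_names]
    )
    landmarks_lge = LandmarkSet(lm_names, lm_coords)
    transform = RigidTransform.from_euler_deg(
        config.rigid_misalignment_deg, config.rigid_misalignment_mm
    )
    landmarks_dixon = LandmarkSet(lm_names, transform.apply_points(lm_coords))

    affine = make_affine(spacing)
    truth = PhantomTruth(
        fibrosis_fraction=achieved,
        cap_directions=cap_dirs,
        cap_angular_radius_rad=theta,
        depot_centers=depot_centers,
        coloc_mode=config.coloc_mode,
        transform_lge_to_dixon=transform,
        seed=config.seed,
    )
    return PhantomCase(
        labels=LabelVolume(labels, affine),
        lge=IntensityVolume(lge, affine),
        landmarks_lge=landmarks_lge,
        landmarks_dixon=landmarks_dixon,
        truth=truth,
        config=config,
    )


def make_cohort(
    n_cases: int,
    base_config: PhantomConfig | None = None,
    coloc_mode: str | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate ``n_cases`` phantoms with per-case seeds derived from ``seed``.

    Child seeds come from a SeedSequence spawn of the master seed, so the
    cohort is reproducible and cases are statistically independent.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    base = base_config if base_config is not None else PhantomConfig()
    mode = coloc_mode if coloc_mode is not None else base.coloc_mode
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cases) % (2**31)
    return [
        make_la_phantom(replace(base, coloc_mode=mode, seed=int(s)))
        for s in child_seeds
    ]
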