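"""Phantom generator: geometry, determinism, truth bookkeeping."""

import numpy as np
import pytest
from dataclasses import replace

from fibrofat import (PhantomConfig, Tissue, make_cohort, make_la_phantom,
                      volumetrize_fat)


def test_spherical_pool_volume_matches_analytic():
    """Spherical LA (semi-axes 20 mm) blood-pool volume within 5% of (4/3)πR³."""
    cfg = PhantomConfig(
        grid_shape=(68, 68, 68), voxel_size_mm=(1.0, 1.0, 1.0),
        la_semiaxes_mm=(20.0, 20.0, 20.0), seed=3,
    )
    case = make_la_phantom(cfg)
    vol = case.labels.mask(Tissue.BLOOD_POOL).sum() * case.labels.voxel_volume_mm3
    analytic = 4.0 / 3.0 * np.pi * 20.0**3
    assert abs(vol - analytic) / analytic < 0.05


def test_no_fat_depots_yields_empty_fat(fast_config):
    cfg = replace(fast_config, n_fat_depots=0, seed=5)
    case = make_la_phantom(cfg)
    assert not case.labels.mask(Tissue.EAT).any()
    fat = volumetrize_fat(case.labels.mask(Tissue.EAT), case.labels.spacing)
    assert fat.n_samples == 0
    assert fat.total_volume_mm3 == 0.0


def test_determinism_bit_identical(fast_config):
    cfg = replace(fast_config, seed=42)
    a = make_la_phantom(cfg)
    b = make_la_phantom(cfg)
    assert np.array_equal(a.labels.data, b.labels.data)
    assert np.array_equal(a.lge.data, b.lge.data)
    assert np.array_equal(a.landmarks_dixon.coords, b.landmarks_dixon.coords)


def test_eat_lies_between_wall_and_pericardium(fast_config):
    case = make_la_phantom(replace(fast_config, seed=9))
    labels = case.labels
    spacing = labels.spacing
    center = np.asarray(labels.shape) * spacing / 2.0
    cfg = case.config
    s_out = np.asarray(cfg.la_semiaxes_mm) + cfg.wall_thickness_mm
    s_peri = s_out + cfg.pericardium_offset_mm
    pts = labels.voxel_centers(labels.mask(Tissue.EAT))
    lvl_out = np.sum(((pts - center) / s_out) ** 2, axis=1)
    lvl_peri = np.sum(((pts - center) / s_peri) ** 2, axis=1)
    assert np.all(lvl_out > 1.0)
    assert np.all(lvl_peri <= 1.0)
    # disjointness with the wall label is structural (single label array),
    # but EAT must never sit inside the blood pool or wall shells
    assert not (labels.mask(Tissue.EAT) & labels.mask(Tissue.WALL)).any()


def test_landmarks_related_by_truth_transform(fast_config):
    case = make_la_phantom(replace(fast_config, seed=2))
    t = case.truth.transform_lge_to_dixon
    mapped = t.apply_points(case.landmarks_lge.coords)
    assert np.allclose(mapped, case.landmarks_dixon.coords, atol=1e-9)


def test_fibrosis_fraction_tracks_request(fast_config):
    """Mean absolute error of achieved vs requested fraction (0.20) < 0.03."""
    errs = []
    for seed in range(20):
        cfg = replace(fast_config, fibrosis_fraction=0.20, seed=seed)
        case = make_la_phantom(cfg)
        errs.append(abs(case.truth.fibrosis_fraction - 0.20))
    assert np.mean(errs) < 0.03


def test_lge_contrast_recovers_delta(fast_config):
    """Fibrotic-minus-normal mean wall intensity ~ planted delta (3 SE)."""
    cfg = replace(fast_config, seed=11, fibrosis_fraction=0.2)
    case = make_la_phantom(cfg)
    wall = case.labels.mask(Tissue.WALL)
    # recover the planted fibrotic voxels from the truth cap geometry
    vals = case.lge.data[wall]
    enhanced = vals > cfg.lge_baseline_mean + cfg.lge_fibrosis_delta / 2.0
    diff = vals[enhanced].mean() - vals[~enhanced].mean()
    n1, n0 = enhanced.sum(), (~enhanced).sum()
    se = cfg.lge_baseline_sd * np.sqrt(1 / n1 + 1 / n0)
    # threshold-selected groups bias the within-group means slightly; allow
    # that truncation on top of the 3-SE sampling band
    assert abs(diff - cfg.lge_fibrosis_delta) < 3 * se + 1.0


def test_cohort_modes_and_determinism(fast_config):
    cases = make_cohort(3, fast_config, coloc_mode="random", seed=7)
    again = make_cohort(3, fast_config, coloc_mode="random", seed=7)
    centers = [c.truth.depot_centers for c in cases]
    for a, b in zip(cases, again):
        assert np.array_equal(a.truth.depot_centers, b.truth.depot_centers)
    # distinct cases have distinct depot layouts
    assert not np.allclose(centers[0], centers[1])

    near = make_cohort(2, fast_config, coloc_mode="near", seed=7)
    for case in near:
        t = case.truth
        spacing = case.labels.spacing
        center = np.asarray(case.labels.shape) * spacing / 2.0
        s = (np.asarray(case.config.la_semiaxes_mm)
             + case.config.wall_thickness_mm + case.config.fat_offset_mm)
        dirs = (t.depot_centers - center) / s
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ang = np.arccos(np.clip(dirs @ t.cap_directions.T, -1, 1)).min(axis=1)
        assert np.all(ang <= t.cap_angular_radius_rad + 1e-9)

    far = make_cohort(2, fast_config, coloc_mode="far", seed=7)
    for case in far:
        t = case.truth
        spacing = case.labels.spacing
        center = np.asarray(case.labels.shape) * spacing / 2.0
        s = (np.asarray(case.config.la_semiaxes_mm)
             + case.config.wall_thickness_mm + case.config.fat_offset_mm)
        dirs = (t.depot_centers - center) / s
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ang = np.arccos(np.clip(dirs @ t.cap_directions.T, -1, 1)).min(axis=1)
        assert np.all(ang > t.cap_angular_radius_rad)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"fibrosis_fraction": 1.5},
        {"voxel_size_mm": (0.0, 1.0, 1.0)},
        {"coloc_mode": "sideways"},
        {"fibrosis_fraction": 0.2, "fibrosis_patch_count": 0},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        PhantomConfig(**kwargs)


def test_grid_overflow_names_structure(fast_config):
    cfg = replace(fast_config, grid_shape=(40, 40, 40))
    with pytest.raises(ValueError, match="pericardial shell"):
        make_la_phantom(cfg)


def test_cohort_requires_positive_n(fast_config):
    with pytest.raises(ValueError):
        make_cohort(0, fast_config, seed=1)
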