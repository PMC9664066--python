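"""d_EAT / V_EAT maps: brute-force agreement, analytic cases, stratification."""

import numpy as np
import pytest

from fibrofat import (ColocMaps, FatVolumeModel, SurfaceMesh, apply_rigid,
                      compute_coloc_maps, compute_deat_map, compute_veat_map,
                      coverage_fraction, stratify_by_fibrosis)
from fibrofat.registration import RigidTransform

from test_registration import _random_rigid


def _mesh_from_points(points, attrs=None):
    return SurfaceMesh(points, np.empty((0, 3), dtype=int), attrs or {})


def brute_force_maps(vertices, fat, radius):
    """O(N*K) reference: same final arithmetic as the indexed path."""
    d = np.empty(len(vertices))
    v = np.empty(len(vertices))
    for i, vert in enumerate(vertices):
        diff = fat.points - vert
        d2 = np.sum(diff * diff, axis=1)
        j = int(np.argmin(d2))
        dj = vert - fat.points[j]
        d[i] = np.sqrt(np.sum(dj * dj))
        idx = np.flatnonzero(np.sqrt(d2) <= radius)
        v[i] = fat.volumes[idx].sum() if len(idx) else 0.0
    return d, v


def test_indexed_equals_brute_force_exactly(rng):
    """k-d-tree maps match the exhaustive scan elementwise (5 random draws)."""
    for _ in range(5):
        verts = rng.uniform(0, 50, size=(300, 3))
        fat = FatVolumeModel(rng.uniform(0, 50, size=(800, 3)),
                             rng.uniform(0.1, 2.0, size=800))
        mesh = _mesh_from_points(verts)
        d = compute_deat_map(mesh, fat)
        v = compute_veat_map(mesh, fat, 5.0)
        d_ref, v_ref = brute_force_maps(verts, fat, 5.0)
        assert np.array_equal(d, d_ref)
        assert np.array_equal(v, v_ref)


def test_vertex_on_fat_sample_has_zero_distance(rng):
    fat = FatVolumeModel(rng.uniform(0, 10, size=(20, 3)), np.ones(20))
    mesh = _mesh_from_points(np.vstack([fat.points[7], [[100, 100, 100]]]))
    d = compute_deat_map(mesh, fat)
    assert d[0] == 0.0


def test_sphere_single_sample_min_max_distance():
    """Sphere surface r=20 at origin, fat sample at (30,0,0): min ~10, max ~50."""
    from conftest import sphere_mask
    from fibrofat import extract_surface

    spacing = (1.0, 1.0, 1.0)
    mask = sphere_mask((46, 46, 46), spacing, (23, 23, 23), 20.0)
    mesh = extract_surface(mask, spacing)
    verts = mesh.vertices - 23.0  # centre at origin
    fat = FatVolumeModel(np.array([[30.0, 0.0, 0.0]]), np.array([1.0]))
    d = compute_deat_map(_mesh_from_points(verts), fat)
    tol = 1.8  # mesh edge length scale
    assert abs(d.min() - 10.0) < tol
    assert abs(d.max() - 50.0) < tol


def test_veat_trivial_cases(rng):
    verts = rng.uniform(0, 10, size=(50, 3))
    mesh = _mesh_from_points(verts)
    # no fat at all -> zero map (valid)
    assert np.array_equal(compute_veat_map(mesh, FatVolumeModel(np.empty((0, 3)), np.empty(0)), 5.0),
                          np.zeros(50))
    # all fat clustered within r of one vertex -> that vertex sees total volume
    cluster = verts[0] + rng.uniform(-1, 1, size=(30, 3))
    fat = FatVolumeModel(cluster, rng.uniform(0.5, 1.5, size=30))
    v = compute_veat_map(mesh, fat, 5.0)
    assert v[0] == fat.volumes.sum()


def test_veat_monotone_in_radius(rng):
    verts = rng.uniform(0, 30, size=(100, 3))
    fat = FatVolumeModel(rng.uniform(0, 30, size=(500, 3)), rng.uniform(0.1, 1, 500))
    mesh = _mesh_from_points(verts)
    prev = np.zeros(100)
    for r in (1.0, 2.5, 5.0, 10.0):
        v = compute_veat_map(mesh, fat, r)
        assert np.all(v >= prev)
        prev = v


def test_maps_invariant_under_common_rigid_motion(rng):
    verts = rng.uniform(0, 30, size=(150, 3))
    fat = FatVolumeModel(rng.uniform(0, 30, size=(400, 3)), rng.uniform(0.1, 1, 400))
    mesh = _mesh_from_points(verts)
    d0 = compute_deat_map(mesh, fat)
    v0 = compute_veat_map(mesh, fat, 5.0)
    t = _random_rigid(rng)
    mesh_t = SurfaceMesh(t.apply_points(verts), np.empty((0, 3), dtype=int))
    fat_t = apply_rigid(t, fat)
    assert np.allclose(compute_deat_map(mesh_t, fat_t), d0, atol=1e-9)
    assert np.allclose(compute_veat_map(mesh_t, fat_t, 5.0), v0, atol=1e-8)


def test_empty_fat_rejected_for_deat():
    mesh = _mesh_from_points(np.zeros((3, 3)))
    with pytest.raises(ValueError, match="no EAT"):
        compute_deat_map(mesh, FatVolumeModel(np.empty((0, 3)), np.empty(0)))


def test_coverage_equivalences(rng):
    """coverage = 1 <=> d_eat <= r <=> v_eat > 0 (away from the boundary)."""
    verts = rng.uniform(0, 40, size=(200, 3))
    fat = FatVolumeModel(rng.uniform(0, 40, size=(300, 3)), rng.uniform(0.1, 1, 300))
    mesh = _mesh_from_points(verts)
    maps = compute_coloc_maps(mesh, fat, 5.0)
    assert np.array_equal(maps.coverage == 1, maps.d_eat <= 5.0)
    assert np.array_equal(maps.coverage == 1, maps.v_eat > 0)


def test_stratification_partition():
    maps = ColocMaps(d_eat=np.arange(10.0), v_eat=np.arange(10.0), radius_mm=5.0)
    fib = np.array([1, 0] * 5, dtype=np.uint8)
    mesh = _mesh_from_points(np.zeros((10, 3)), {"fibrotic": fib})
    s = stratify_by_fibrosis(maps, mesh)
    assert s.n_fibrotic == 5 and s.n_nonfibrotic == 5
    assert s.n_fibrotic + s.n_nonfibrotic == 10
    assert s.empty_group is None


def test_stratification_flags_empty_group():
    maps = ColocMaps(d_eat=np.ones(4), v_eat=np.ones(4), radius_mm=5.0)
    mesh = _mesh_from_points(np.zeros((4, 3)), {"fibrotic": np.ones(4, dtype=np.uint8)})
    s = stratify_by_fibrosis(maps, mesh)
    assert s.empty_group == "nonfibrotic"
    assert s.n_fibrotic == 4


def test_coverage_fraction_hand_case():
    """6 vertices: 3 of 4 fibrotic covered, 1 of 2 non-fibrotic -> 75% vs 50%."""
    v_eat = np.array([1.0, 2.0, 3.0, 0.0, 4.0, 0.0])
    fib = np.array([1, 1, 1, 1, 0, 0], dtype=np.uint8)
    maps = ColocMaps(d_eat=np.zeros(6), v_eat=v_eat, radius_mm=5.0)
    mesh = _mesh_from_points(np.zeros((6, 3)), {"fibrotic": fib})
    cov = coverage_fraction(stratify_by_fibrosis(maps, mesh))
    assert cov["fibrotic"] == pytest.approx(75.0)
    assert cov["nonfibrotic"] == pytest.approx(50.0)


def test_sphere_shell_distance_band(rng):
    """Fat shell at gap D around an LA sphere: all d_eat in [D-tol, D+t+tol]."""
    from conftest import shell_mask, sphere_mask
    from fibrofat import extract_surface, volumetrize_fat

    spacing = (1.0, 1.0, 1.0)
    shape = (60, 60, 60)
    c = (30.0, 30.0, 30.0)
    la = sphere_mask(shape, spacing, c, 15.0)
    shell = shell_mask(shape, spacing, c, 20.0, 22.0)  # gap 5, thickness 2
    mesh = extract_surface(la, spacing)
    fat = volumetrize_fat(shell, spacing, target_spacing_mm=1.0)
    d = compute_deat_map(mesh, fat)
    tol = np.sqrt(3.0)  # sample spacing diagonal
    assert d.min() >= 5.0 - tol
    assert d.max() <= 5.0 + 2.0 + tol
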