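"""Nonparametric group comparison, cohort aggregation and volume indexing.

The fibrotic vs non-fibrotic metric samples are compared with the two-sided
Mann-Whitney U test. Small tie-free problems (n_a + n_b <= 20) use the exact
null distribution (full enumeration by dynamic programming over rank subsets);
larger or tied problems use the normal approximation with tie-corrected
variance and a 0.5 continuity correction. Summaries are median and IQR with
quartiles by linear interpolation of order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, erfc, sqrt

import numpy as np


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]  # (Q1, Q3)
    iqr_b: tuple[float, float]
    u_statistic: float
    p_value: float
    method: str = "exact"


@dataclass
class CohortSummary:
    """Pooled fibrotic/non-fibrotic comparison across a cohort of cases."""

    n_cases: int
    d_eat: GroupComparison
    v_eat: GroupComparison
    coverage_fibrotic_pct: float
    coverage_nonfibrotic_pct: float
    per_case: list[dict] = field(default_factory=list)
    aggregation: str = "pooled"


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with quartiles by linear interpolation of order stats."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _exact_sf_counts(n_a: int, n_b: int) -> np.ndarray:
    """Null distribution of the rank sum of sample a: counts[r] = number of
    ways to choose n_a of the ranks 1..n_a+n_b summing to r (tie-free null)."""
    n = n_a + n_b
    max_sum = n_a * n + n_a * (n_a + 1) // 2  # generous upper bound
    counts = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n_a), 0, -1):
            counts[k, rank:] += counts[k - 1, :-rank or None]
    return counts[n_a]


def mann_whitney_u(sample_a, sample_b) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    U is computed from mid-rank sums (ties allowed). The reported statistic is
    U of ``sample_a``; the complement identity U(a,b) + U(b,a) = n_a * n_b
    holds by construction. All-identical input yields p = 1.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n_a + n_b)
    sorted_vals = pooled[order]
    # mid-ranks for ties
    i = 0
    base = np.arange(1, n_a + n_b + 1, dtype=float)
    tie_sizes = []
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = base[i : j + 1].mean()
        if j > i:
            tie_sizes.append(j - i + 1)
        i = j + 1
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    has_ties = bool(tie_sizes)
    if not has_ties and n_a + n_b <= 20:
        # exact two-sided p by full enumeration of rank assignments
        counts = _exact_sf_counts(n_a, n_b)
        total = comb(n_a + n_b, n_a)
        u_all = np.arange(len(counts)) - n_a * (n_a + 1) / 2.0
        valid = (u_all >= 0) & (u_all <= n_a * n_b)
        probs = counts[valid] / total
        u_vals = u_all[valid]
        u_lo = min(u_a, n_a * n_b - u_a)
        p = float(probs[(u_vals <= u_lo) | (u_vals >= n_a * n_b - u_lo)].sum())
        method = "exact"
    else:
        n = n_a + n_b
        mean_u = n_a * n_b / 2.0
        tie_term = sum(t**3 - t for t in tie_sizes)
        var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_u <= 0:
            p = 1.0
        else:
            z = (abs(u_a - mean_u) - 0.5) / sqrt(var_u)
            z = max(z, 0.0)
            p = erfc(z / sqrt(2.0))
        method = "normal_approx"
    p = min(1.0, max(p, np.finfo(float).tiny))

    med_a, q1_a, q3_a = median_iqr(a)
    med_b, q1_b, q3_b = median_iqr(b)
    return GroupComparison(
        n_a=n_a, n_b=n_b,
        median_a=med_a, median_b=med_b,
        iqr_a=(q1_a, q3_a), iqr_b=(q1_b, q3_b),
        u_statistic=float(u_a), p_value=p, method=method,
    )


def body_surface_area_m2(height_cm: float, weight_kg: float, formula: str = "mosteller") -> float:
    """BSA in m^2; Mosteller by default, DuBois available."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return sqrt(height_cm * weight_kg / 3600.0)
    if formula == "dubois":
        return 0.007184 * height_cm**0.725 * weight_kg**0.425
    raise ValueError(f"unknown BSA formula {formula!r}")


def volume_and_index(
    mask: np.ndarray,
    spacing,
    z_slab_mm: tuple[float, float] | None = None,
    height_cm: float | None = None,
    weight_kg: float | None = None,
    origin_z_mm: float = 0.0,
    bsa_formula: str = "mosteller",
) -> tuple[float, float | None]:
    """Mask volume in mL, optionally restricted to a z-slab and BSA-indexed.

    Volume = voxel count x voxel volume (1 mL = 1000 mm^3); the slab selects
    voxels whose centre z lies in the closed interval. Index = volume / BSA.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if z_slab_mm is not None:
        z_lo, z_hi = z_slab_mm
        z_centers = np.arange(mask.shape[2]) * spacing[2] + origin_z_mm
        grid_lo, grid_hi = z_centers[0], z_centers[-1]
        if z_hi < grid_lo or z_lo > grid_hi:
            raise ValueError(
                f"z-slab [{z_lo}, {z_hi}] mm lies outside the grid z-range "
                f"[{grid_lo}, {grid_hi}] mm"
            )
        keep = (z_centers >= z_lo) & (z_centers <= z_hi)
        mask = mask[:, :, keep]
    volume_ml = float(mask.sum()) * float(np.prod(spacing)) / 1000.0
    index = None
    if height_cm is not None and weight_kg is not None:
        index = volume_ml / body_surface_area_m2(height_cm, weight_kg, bsa_formula)
    return volume_ml, index


def aggregate_cohort(cases, aggregation: str = "pooled") -> CohortSummary:
    """Combine per-case stratified samples into a cohort-level comparison.

    ``pooled`` concatenates vertex-level values across cases before testing
    (each surface point contributes one observation); ``per_case`` reduces each
    case to its group medians first and tests those. Cases with an empty group
    are refused.
    """
    cases = list(cases)
    valid = [c for c in cases if c.empty_group is None]
    if not valid:
        raise ValueError("no case has both fibrotic and non-fibrotic vertices")
    if aggregation == "pooled":
        d_f = np.concatenate([c.d_eat_fibrotic for c in valid])
        d_n = np.concatenate([c.d_eat_nonfibrotic for c in valid])
        v_f = np.concatenate([c.v_eat_fibrotic for c in valid])
        v_n = np.concatenate([c.v_eat_nonfibrotic for c in valid])
        cov_f = np.concatenate([c.coverage_fibrotic for c in valid])
        cov_n = np.concatenate([c.coverage_nonfibrotic for c in valid])
    elif aggregation == "per_case":
        d_f = np.array([np.median(c.d_eat_fibrotic) for c in valid])
        d_n = np.array([np.median(c.d_eat_nonfibrotic) for c in valid])
        v_f = np.array([np.median(c.v_eat_fibrotic) for c in valid])
        v_n = np.array([np.median(c.v_eat_nonfibrotic) for c in valid])
        cov_f = np.array([c.coverage_fibrotic.mean() for c in valid])
        cov_n = np.array([c.coverage_nonfibrotic.mean() for c in valid])
    else:
        raise ValueError(f"unknown aggregation mode {aggregation!r}")
    per_case = [
        {
            "n_fibrotic": c.n_fibrotic,
            "n_nonfibrotic": c.n_nonfibrotic,
            "median_d_eat_fibrotic": float(np.median(c.d_eat_fibrotic)),
            "median_d_eat_nonfibrotic": float(np.median(c.d_eat_nonfibrotic)),
        }
        for c in valid
    ]
    return CohortSummary(
        n_cases=len(valid),
        d_eat=mann_whitney_u(d_f, d_n),
        v_eat=mann_whitney_u(v_f, v_n),
        coverage_fibrotic_pct=100.0 * float(np.asarray(cov_f, dtype=float).mean()),
        coverage_nonfibrotic_pct=100.0 * float(np.asarray(cov_n, dtype=float).mean()),
        per_case=per_case,
        aggregation=aggregation,
    )
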