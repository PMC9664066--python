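import numpy as np
import pytest

from fibrofat import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_config():
    """Coarser phantom grid for cohort-level tests (1.25 mm isotropic)."""
    return PhantomConfig(
        grid_shape=(72, 72, 72),
        voxel_size_mm=(1.25, 1.25, 1.25),
    )


def sphere_mask(shape, spacing, center_mm, radius_mm):
    """Voxel-centre sphere mask used by the analytic-geometry tests."""
    idx = np.indices(shape).astype(float)
    centers = np.stack([idx[i] * spacing[i] for i in range(3)], axis=-1)
    d2 = np.sum((centers - np.asarray(center_mm)) ** 2, axis=-1)
    return d2 <= radius_mm**2


def shell_mask(shape, spacing, center_mm, r_inner_mm, r_outer_mm):
    idx = np.indices(shape).astype(float)
    centers = np.stack([idx[i] * spacing[i] for i in range(3)], axis=-1)
    d2 = np.sum((centers - np.asarray(center_mm)) ** 2, axis=-1)
    return (d2 > r_inner_mm**2) & (d2 <= r_outer_mm**2)
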