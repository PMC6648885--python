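import numpy as np
import pytest

from qsmradiomics import CohortSpec, VoiMask, VoxelGrid, generate_feature_table


def random_voi(seed, shape=(6, 6, 4), n_levels=4, density=0.6):
    """Small random VOI: intensities, a random mask and its discretization."""
    rng = np.random.default_rng(seed)
    values = rng.normal(0.05, 0.02, shape)
    mask = rng.random(shape) < density
    if mask.sum() < 2:  # guarantee a usable VOI
        mask.flat[:2] = True
    return VoxelGrid(values, (0.86, 0.86, 1.0)), VoiMask(mask.astype(np.uint8))


def line_voi(levels_1d, spacing=(1.0, 1.0, 1.0)):
    """A 1 x 1 x n VOI carrying the given gray levels along the slice axis."""
    n = len(levels_1d)
    values = np.asarray(levels_1d, dtype=float).reshape(1, 1, n)
    mask = np.ones((1, 1, n), dtype=np.uint8)
    return VoxelGrid(values, spacing), VoiMask(mask)


@pytest.fixture(scope="session")
def gaussian_table():
    """Feature table drawn from the reported class-conditional Gaussians."""
    return generate_feature_table(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced image-level cohort for pipeline-shape tests."""
    from qsmradiomics import generate_cohort

    return generate_cohort(
        CohortSpec(n_ipd=12, n_hc=12, grid_shape=(40, 40, 8), seed=5)
    )
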