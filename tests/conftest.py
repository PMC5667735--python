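import numpy as np
import pytest

from saliency3d import (
    CubeGrid,
    MultiScaleConfig,
    PhantomSpec,
    compute_saliency,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48-voxel phantom: fast enough for per-module tests."""
    spec = PhantomSpec(size=48, tumour_radius=7, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_config():
    """Two-scale config matching the 48-voxel phantom (divisor 8)."""
    return MultiScaleConfig(scales=(4, 8), weights=(0.5, 0.5))


@pytest.fixture(scope="session")
def default_phantom_run():
    """The default 96-voxel phantom (seed 42) pushed through the full pipeline."""
    seqs, gt = generate_phantom(PhantomSpec())
    saliency, record = compute_saliency(seqs)
    return seqs, gt, saliency, record


def random_cube_grids(n: int, max_dim: int = 6, seed: int = 0):
    """Seeded stream of random CubeGrids with Lab-like value ranges."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        dims = rng.integers(2, max_dim + 1, size=3)
        means = np.empty((*dims, 3))
        means[..., 0] = rng.uniform(0, 100, dims)
        means[..., 1] = rng.uniform(-80, 80, dims)
        means[..., 2] = rng.uniform(-80, 80, dims)
        yield CubeGrid(k=1, means=means)
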