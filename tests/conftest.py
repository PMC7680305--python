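import numpy as np
import pytest

from lnrad.images import DiscretizedVOI, ImageVolume, SegmentationMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ball(radius_mm=10.0, spacing=(1.0, 1.0, 1.0), margin=3, value=50.0, noise=0.0, seed=0):
    """A digital ball image/mask pair on an isotropic-by-default grid."""
    sp = np.asarray(spacing, float)
    half = int(np.ceil(radius_mm / sp.min())) + margin
    n = 2 * half + 1
    ax = [(np.arange(n) - half) * s for s in sp]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij")
    mask = zz**2 + yy**2 + xx**2 <= radius_mm**2
    img = np.full((n, n, n), value)
    if noise:
        img = img + noise * np.random.default_rng(seed).standard_normal(img.shape)
    return ImageVolume(img, tuple(sp)), SegmentationMask(mask, tuple(sp))


@pytest.fixture
def ball_pair():
    return make_ball(radius_mm=10.0)


def grid_voi(grid: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> DiscretizedVOI:
    """Wrap a small integer gray-level grid (0 = outside) as a DiscretizedVOI."""
    grid = np.asarray(grid, dtype=np.int64)
    bins = grid[grid > 0]
    return DiscretizedVOI(
        bins=bins,
        bin_width=1.0,
        n_bins=int(grid.max()) if grid.max() > 0 else 1,
        min_intensity=0.0,
        grid=grid,
        spacing=spacing,
    )


def random_voi(rng, shape=(4, 4, 4), n_levels=4, p_mask=0.8) -> DiscretizedVOI:
    grid = rng.integers(1, n_levels + 1, size=shape)
    grid[rng.random(shape) > p_mask] = 0
    if (grid > 0).sum() < 2:
        grid[0, 0, 0] = 1
        grid[0, 0, 1] = n_levels
    return grid_voi(grid)
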