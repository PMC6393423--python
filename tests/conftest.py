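import numpy as np
import pytest

from tumormorph import BinaryMask


def make_disk(radius: int, margin: int = 16) -> BinaryMask:
    side = 2 * (radius + margin)
    c = side / 2.0 - 0.5
    yy, xx = np.mgrid[0:side, 0:side]
    return BinaryMask(np.hypot(yy - c, xx - c) <= radius)


def make_blob(seed: int, side: int = 160) -> BinaryMask:
    """Random simply-shaped blob of >= 1024 px (smoothed-noise superlevel set)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal((side, side)), side / 8)
    grid = field > np.quantile(field, 0.75)
    lab, n = ndimage.label(grid)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
    grid = lab == (1 + int(np.argmax(sizes)))
    assert grid.sum() >= 1024
    return BinaryMask(grid)


def sierpinski(levels: int) -> BinaryMask:
    cell = np.array([[1, 1], [1, 0]], dtype=bool)
    m = np.ones((1, 1), dtype=bool)
    for _ in range(levels):
        m = np.kron(m, cell)
    return BinaryMask(m)


@pytest.fixture
def disk200() -> BinaryMask:
    return make_disk(200)
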