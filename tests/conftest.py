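import numpy as np
import pytest

from synq.io import ImageStack


def star_mask(shape=(64, 64), r0=22.0, harmonics=((2, 0.08), (3, 0.05)), phases=None, rng=None):
    """A random star-shaped (about its center) blob mask for radial tests."""
    rng = rng or np.random.default_rng(0)
    if phases is None:
        phases = rng.uniform(0, 2 * np.pi, len(harmonics))
    cy, cx = (shape[0] - 1) / 2 + rng.uniform(-1, 1), (shape[1] - 1) / 2 + rng.uniform(-1, 1)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = rows - cy, cols - cx
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    boundary = np.full(shape, r0)
    for (k, a), ph in zip(harmonics, phases):
        boundary = boundary + r0 * a * np.cos(k * theta + ph)
    return r <= boundary


@pytest.fixture
def disk_stack():
    """A 2-channel uniform-disk scene as a ready ImageStack."""
    from synq.synthetic import make_cell_scene

    stack, truth = make_cell_scene(
        {"a": {"kind": "uniform", "intensity": 50.0}, "b": {"kind": "uniform", "intensity": 80.0}}
    )
    return stack, truth


def stack_from_planes(planes, axes="ZYX", pixel_size_um=0.1, **kw):
    return ImageStack.from_array(np.asarray(planes, float), axes, pixel_size_um=pixel_size_um, **kw)
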