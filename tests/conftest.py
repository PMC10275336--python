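import numpy as np
import pytest

from fasciseg.synthetic import SynthParams, generate_stack


@pytest.fixture(scope="session")
def small_stack():
    """A small default-composition phantom stack (12 fascicles, 10 slices)."""
    return generate_stack(SynthParams(image_size=256, n_slices=10, seed=42), nerve_id="fix")


@pytest.fixture(scope="session")
def desk_stack():
    """A desk-scale easy phantom (128 px, 4 fascicles)."""
    return generate_stack(SynthParams.desk_scale(seed=7, n_slices=8), nerve_id="desk")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask_pair(rng, size=32, n_blobs=4):
    """A correlated truth/prediction mask pair with blobs that overlap,
    disappear, split or merge at random — stresses the instance metrics."""
    truth = np.zeros((size, size), dtype=bool)
    pred = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(rng.integers(1, n_blobs + 1)):
        r = rng.integers(2, 6)
        cy, cx = rng.integers(r, size - r, size=2)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        truth |= blob
        mode = rng.random()
        if mode < 0.15:
            continue  # missed fascicle
        dy, dx = rng.integers(-3, 4, size=2)
        shifted = np.roll(np.roll(blob, dy, axis=0), dx, axis=1)
        if mode < 0.35:  # split into two predicted parts
            left = shifted.copy()
            left[:, cx:] = False
            right = shifted & ~left
            pred |= left
            pred |= np.roll(right, 2, axis=1)
        else:
            pred |= shifted
    for _ in range(rng.integers(0, 3)):  # added fascicles
        r = rng.integers(1, 4)
        cy, cx = rng.integers(r, size - r, size=2)
        pred |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return truth, pred
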