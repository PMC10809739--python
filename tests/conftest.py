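import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_image(seed: int, shape=(64, 64)) -> np.ndarray:
    return np.random.default_rng(seed).random(shape)


def structured_image(kind: str, shape=(64, 64)) -> np.ndarray:
    """Deterministic non-random test images: edges, gradients, blobs."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    if kind == "vstep":
        return (xx >= cols // 2).astype(float)
    if kind == "hstep":
        return (yy >= rows // 2).astype(float)
    if kind == "gradient":
        return (xx + yy) / (rows + cols - 2)
    if kind == "blob":
        cy, cx = (rows - 1) / 2, (cols - 1) / 2
        return np.exp(-(((yy - cy) / (0.2 * rows)) ** 2 + ((xx - cx) / (0.2 * cols)) ** 2))
    raise ValueError(kind)
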