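import numpy as np
import pytest

from cfoscount.overlap import train_overlap_model

#: Reduced training budget so the whole suite stays fast on one CPU; the
#: classifier reaches its accuracy bars already at this size.
TRAIN_SEED = 2025
TRAIN_KWARGS = dict(seed=TRAIN_SEED, epochs=8, n_per_class=400)


@pytest.fixture(scope="session")
def overlap_model():
    """One trained overlap classifier shared by the whole session."""
    return train_overlap_model(**TRAIN_KWARGS)


@pytest.fixture()
def rng():
    return np.random.default_rng(17)


def rasterize_disk(radius: float, center=None, size: int | None = None) -> np.ndarray:
    """Boolean disk mask: pixel centres within ``radius`` of the centre."""
    if size is None:
        size = int(2 * radius) + 11
    if center is None:
        center = (size // 2, size // 2)
    cy, cx = center
    yy, xx = np.mgrid[:size, :size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
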