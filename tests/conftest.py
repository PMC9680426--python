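import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from foragekit.core import CLASS_A, CLASS_B, Display, ForagingParams, Item

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_display(positions, classes=None):
    """Build a display from raw (x, y) tuples; classes alternate A/B by default."""
    if classes is None:
        classes = [CLASS_A if k % 2 == 0 else CLASS_B for k in range(len(positions))]
    return Display(
        Item(item_id=k, x=float(x), y=float(y), item_class=c)
        for k, ((x, y), c) in enumerate(zip(positions, classes))
    )


@pytest.fixture
def square_display():
    """Four items on the corners of a small inner square, two per class."""
    return make_display(
        [(0.2, 0.2), (0.8, 0.2), (0.8, 0.8), (0.2, 0.8)],
        [CLASS_A, CLASS_B, CLASS_A, CLASS_B],
    )


@pytest.fixture
def uniform_params():
    return ForagingParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
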