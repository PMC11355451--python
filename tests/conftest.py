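import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from stackalign import FrameStack, band_limited_texture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def textured_frame(rng):
    """Band-limited periodic texture: cyclic shifts of it are exact, and
    it carries gradient energy everywhere."""
    return band_limited_texture((128, 128), 1.5, rng)


@pytest.fixture
def textured_stack(textured_frame):
    """Stack of cumulative integer cyclic shifts of one texture; the
    ground-truth step is (+1, 0) per frame (content moves right)."""
    frames = [np.roll(textured_frame, t, axis=1) for t in range(4)]
    return FrameStack(np.stack(frames)), np.array([[1.0, 0.0]] * 3)


def cyclic_shift(frame, dx, dy):
    """Integer-roll oracle in the package's (dx, dy) convention: content
    moves dx columns rightward and dy rows downward."""
    return np.roll(frame, (int(dy), int(dx)), axis=(0, 1))
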