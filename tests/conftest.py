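import numpy as np
import pytest

from cervimage import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One modest phantom shared by read-only tests (600 px wide, seed 7)."""
    spec = PhantomSpec(width_px=600, height_px=220, seed=7)
    channels, boundaries, truth = generate_phantom(spec)
    return spec, channels, boundaries, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
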