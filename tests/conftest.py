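import numpy as np
import pytest

from fgfusion import FocusPairSpec, PhantomSpec, make_focus_pair, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20210610)


@pytest.fixture
def random_image(rng):
    """16x16 seeded uniform image, the general-purpose small fixture."""
    return rng.uniform(0.0, 1.0, (16, 16))


@pytest.fixture(scope="session")
def phantom():
    """One 128x128 phantom shared across read-only tests."""
    return make_phantom(PhantomSpec(size=128, seed=3))


@pytest.fixture(scope="session")
def focus_pair(phantom):
    """Half-split complementary-focus pair derived from the phantom."""
    a, b, mask = make_focus_pair(
        phantom, FocusPairSpec(blur_sigma=2.0, mask_kind="half-split", seed=3)
    )
    return phantom, a, b, mask
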