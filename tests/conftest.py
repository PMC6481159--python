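import numpy as np
import pytest

from sshos.phantom import Lesion, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def flat_speckle():
    """Flat 128x128 field of 4-look speckle around level 0.5."""
    spec = PhantomSpec(
        height=128, width=128, background_level=0.5, lesions=(),
        speckle_looks=4.0, random_seed=7,
    )
    img, _ = make_phantom(spec)
    return img


@pytest.fixture(scope="session")
def lesion_phantom():
    """Default 256x256 phantom with one hypoechoic lesion + truth mask."""
    return make_phantom(PhantomSpec(random_seed=3))


@pytest.fixture(scope="session")
def small_lesion_phantom():
    """Smaller phantom (121x121, one lesion) for faster pipeline tests."""
    spec = PhantomSpec(
        height=121, width=121,
        lesions=(Lesion(60.0, 60.0, 18.0, 24.0, 15.0, 0.25),),
        random_seed=11,
    )
    return make_phantom(spec)
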