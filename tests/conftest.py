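import numpy as np
import pytest

from cinescar.phantom import PhantomConfig, generate_study


@pytest.fixture(scope="session")
def scar_study():
    return generate_study(PhantomConfig(scar_present=True, seed=7))


@pytest.fixture(scope="session")
def healthy_study():
    return generate_study(PhantomConfig(scar_present=False, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def textured_image():
    """Smooth random field with phantom-like contrast (for flow/registration)."""
    import scipy.ndimage as ndi

    gen = np.random.default_rng(42)
    img = ndi.gaussian_filter(gen.normal(0.0, 1.0, (64, 64)), 3.0)
    return img / img.std() * 0.25 + 0.5
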