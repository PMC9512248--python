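import numpy as np
import pytest

from shadowedge.gabor_frontend import GaborBankSpec, build_bank


@pytest.fixture(scope="session")
def bank_spec():
    return GaborBankSpec()


@pytest.fixture(scope="session")
def bank(bank_spec):
    return build_bank(bank_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def vertical_step_patch():
    """Sharp vertical step, dark left, with its canonical partition."""
    pixels = np.full((40, 40), 0.25)
    pixels[:, 20:] = 0.75
    left = np.zeros((40, 40), dtype=bool)
    left[:, :19] = True
    right = np.zeros((40, 40), dtype=bool)
    right[:, 20:] = True
    edge = np.zeros((40, 40), dtype=bool)
    edge[:, 19] = True
    from shadowedge.containers import ImagePatch

    return ImagePatch(
        pixels=pixels, region_masks=(left, right), edge_mask=edge,
        aligned=True,
    )
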