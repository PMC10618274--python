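import numpy as np
import pytest

from tomodensity import PhantomSpec, make_breast_mask, make_slice, make_volume


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom geometry: 8 slices of 128x100 pixels."""
    return PhantomSpec(image_shape=(128, 100), n_slices=8, cbt_mm=8.0, seed=11)


@pytest.fixture(scope="session")
def small_volume(small_spec):
    return make_volume(small_spec)


@pytest.fixture(scope="session")
def adipose_image():
    """A pure-adipose 256x200 slice (target PD forced to zero)."""
    spec = PhantomSpec(
        image_shape=(256, 200),
        n_slices=4,
        cbt_mm=4.0,
        dense_fraction_profile=(0.0, 0.0, 0.0),
        seed=5,
    )
    img, dense = make_slice(spec, 1, seed=5)
    assert not dense.any()
    return img


@pytest.fixture(scope="session")
def default_mask():
    return make_breast_mask((128, 100), "left")
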