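import numpy as np
import pytest

from lumenquant.phantom import PhantomConfig, generate_phantom

# a small stack: same in-plane spacing and dissection topology as the
# default, but quick enough to regenerate freely inside tests
SMALL = PhantomConfig(
    grid_size=(96, 96, 30),
    lumen_radius_mm=15.0,
    split_slice=8,
    merge_slice=22,
    noise_sd=10.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def noiseless_phantom():
    import dataclasses

    cfg = dataclasses.replace(SMALL, noise_sd=0.0)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def noisy_phantom():
    return generate_phantom(SMALL)


@pytest.fixture(scope="session")
def default_phantom():
    """The full-size default stack (split 40 / merge 100, 140 slices)."""
    return generate_phantom(PhantomConfig(seed=3))


def metrics_row(slice_index, duct, value=None, **overrides):
    """Hand-build a CrossSectionMetrics with every field defaulting to `value`."""
    from lumenquant.geometry import CrossSectionMetrics

    fields = dict(
        D_v=value, D_h=value, D_F=value, area=value, perimeter=value,
        D_Hy=value, B_AV=value,
    )
    fields.update(overrides)
    return CrossSectionMetrics(slice_index=slice_index, duct=duct, **fields)
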