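import numpy as np
import pytest

import whiskbroom as wb


@pytest.fixture
def pose():
    return wb.GimbalState(pan_step=0, tilt_step=0)


@pytest.fixture
def instrument():
    """Default noisy virtual unit, seed 0."""
    return wb.default_instrument(0)


@pytest.fixture
def instrument_noisefree():
    return wb.default_instrument(0).noiseless()


@pytest.fixture
def instrument_exact():
    """Noise-free and unquantised: the continuous analytic forward chain."""
    m = wb.default_instrument(0).noiseless()
    m.quantise = False
    return m


@pytest.fixture
def flat_scene():
    return wb.make_reference_scene("flat", level=0.15)


@pytest.fixture
def hdr_scene():
    return wb.make_reference_scene("hdr-night")


def hdr_plan(**overrides):
    """Small grid covering all hdr-night sources (6 rows x 20 cols, ~6 deg)."""
    params = dict(
        pan_start=0,
        pan_stop=646,
        pan_step_size=34,
        tilt_start=-34,
        tilt_stop=136,
        tilt_step_size=34,
    )
    params.update(overrides)
    return wb.ScanPlan(**params)


@pytest.fixture
def linear_sensor():
    """Unit-sensitivity, zero-dark, perfectly linear, noise-free sensor."""
    m = wb.default_instrument(
        0,
        nonlinearity_a=1.0,
        nonlinearity_b=0.0,
        dark_offset=0.0,
        dark_slope=0.0,
        noise_gain=0.0,
        read_noise=0.0,
        sensitivity=np.ones(288),
    )
    m.quantise = False
    return m
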