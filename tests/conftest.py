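import numpy as np
import pytest

import ocuvib as ov


@pytest.fixture(scope="session")
def flap_model():
    return ov.build_flap(ov.FlapConfig())


@pytest.fixture(scope="session")
def flap_frf(flap_model):
    return ov.sweep(flap_model, 50.0, 750.0, 5.0)


@pytest.fixture(scope="session")
def globe_model():
    return ov.build_globe(ov.GlobeConfig())


@pytest.fixture(scope="session")
def globe_frf_1hz(globe_model):
    """The nominal whole-globe FRF at the finest tested resolution (1 Hz)."""
    return ov.sweep(globe_model, 50.0, 510.0, 1.0)
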