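import numpy as np
import pytest

from fiberscope import optics, thermal


@pytest.fixture(scope="session")
def presets():
    return optics.load_presets()


@pytest.fixture(scope="session")
def imaging_protocol():
    """The standard scanned-imaging protocol: 10 um spot, 500 um FOV, 5 Hz."""
    return thermal.IlluminationProtocol(
        fov_diameter=500.0,
        frame_rate=5.0,
        spot_fwhm=10.0,
        scanning_power=195.0,
        depth=120.0,
        n_frames=16,
    )


@pytest.fixture(scope="session")
def trace_195(imaging_protocol):
    """One shared full-protocol simulation at 195 mW (reduced sampling).

    2500 samples/frame agrees with the 10^4 default to better than 0.5%
    (checked by halving/doubling); shared session-wide because several
    properties are read off the same trace.
    """
    return thermal.simulate_temperature_rise(
        imaging_protocol, samples_per_frame=2500
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
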