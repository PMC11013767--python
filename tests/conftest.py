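import numpy as np
import pytest

from radarhrv.vitalsim import HeartbeatParams, RespirationParams


@pytest.fixture()
def resp_params() -> RespirationParams:
    return RespirationParams(amplitude_mm=8.0, rate_hz=0.25,
                             inhale_exhale_ratio=2.0, tau_s=1.2)


@pytest.fixture()
def heart_params() -> HeartbeatParams:
    return HeartbeatParams(amplitude_mm=0.4, rate_hz=1.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
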