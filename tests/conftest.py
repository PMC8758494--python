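import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spikegamma as sg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

FS = 5000.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


def make_tone(freq: float, duration: float = 10.0, amp: float = 1.0,
              fs: float = FS, units: str = "mV") -> sg.TimeSeries:
    t = np.arange(int(round(duration * fs))) / fs
    return sg.TimeSeries(amp * np.sin(2 * np.pi * freq * t), fs, units=units)


@pytest.fixture(scope="session")
def tone30() -> sg.TimeSeries:
    return make_tone(30.0, duration=60.0)


@pytest.fixture(scope="session")
def quiet_lfp_params() -> sg.GammaLfpParams:
    """Gamma LFP with a steady carrier (no frequency wander) and mild noise,
    the regime for estimator-recovery checks."""
    return sg.GammaLfpParams(
        duration=20.0, carrier_freq=30.0, carrier_amp=0.05,
        amp_jitter_sd=0.2, freq_jitter_sd=0.0, noise_amp=0.02, seed=0,
    )


@pytest.fixture(scope="session")
def psc_template() -> sg.EventTemplate:
    params = sg.SynapticTraceParams()
    return sg.build_template(
        [sg.psc_kernel(params)] * 20, params.sampling_rate, params.polarity
    )
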