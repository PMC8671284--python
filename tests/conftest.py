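import numpy as np
import pytest

import aortuq as aq


@pytest.fixture(scope="session")
def pre_fixture():
    return aq.patient_fixture("pre")


@pytest.fixture(scope="session")
def pre_inflow(pre_fixture):
    return aq.make_inflow(pre_fixture.pulse, 512)


@pytest.fixture(scope="session")
def smooth_inflow():
    """Infinitely smooth periodic pulse (sin² lobe over the whole cycle)."""
    T = 0.7
    t = np.linspace(0.0, T, 4096, endpoint=False)
    q = 60.0 + 300.0 * np.sin(np.pi * t / T) ** 2
    return aq.Waveform(times=t, values=q, period=T, kind="flow", unit="cm3/s")
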