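import numpy as np
import pytest

from windkessel3 import WK3Params, Waveform
from windkessel3.synthetic import DEFAULT_TEMPLATES, make_flow_template


def sinusoid_flow(qbar=5.0, amp=2.0, period=0.95, n=200, phase=0.0):
    t = np.arange(n) / n * period
    omega = 2 * np.pi / period
    return Waveform(time=t, value=qbar + amp * np.sin(omega * t + phase),
                    period=period, quantity="flow")


@pytest.fixture(scope="session")
def carotid_flow():
    """Dimensional carotid-template flow: mean 7.63 mL/s, T = 0.952 s."""
    template = make_flow_template(DEFAULT_TEMPLATES["cca"])
    return template.to_waveform(mean=7.63, period=0.952)


@pytest.fixture(scope="session")
def carotid_params():
    """Cohort-median carotid WK3 parameters."""
    return WK3Params(r1=1.14, r2=10.35, c=0.04)


def random_params(rng, period=1.0):
    """Physiologically-ranged random WK3 parameters."""
    rtot = rng.uniform(5.0, 40.0)
    r1norm = rng.uniform(0.02, 0.5)
    cnorm = rng.uniform(0.1, 3.0)
    return WK3Params(r1=r1norm * rtot, r2=(1 - r1norm) * rtot,
                     c=cnorm * period / rtot)
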