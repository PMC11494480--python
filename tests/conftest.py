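import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hopfbundle as hb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Reference parameter set."""
    return hb.Parameters()


@pytest.fixture(scope="session")
def iso_params():
    """Isochronous oscillator (beta = -1)."""
    return hb.Parameters(b_imag=0.0)


@pytest.fixture(scope="session")
def selftuned_trace(params):
    """Long unforced run with self-tuning active, at the tight default
    solver tolerances; transients have died out well before t=150."""
    return hb.integrate(params, t_span=(0.0, 300.0))


def make_tone_trace(amplitude=1.0, omega=2 * np.pi, phase0=0.0, t_end=50.0,
                    dt=0.01, mu=0.0):
    """Synthetic pure-rotation trace z = A exp(i(omega t + phase0))."""
    t = np.arange(0.0, t_end, dt)
    ph = omega * t + phase0
    return hb.Trace(t, amplitude * np.cos(ph), amplitude * np.sin(ph),
                    np.full_like(t, mu))
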