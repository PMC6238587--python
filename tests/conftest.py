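"""Shared fixtures: simulated traces reused across test modules.

Session scope keeps the expensive ODE simulations to one run each; tests
must not mutate fixture traces (processing functions return copies).
"""

import numpy as np
import pytest

from oxykin.presets import ERO1A_PDI, ERO1B_PDI, ERV1P
from oxykin.simulate import SimulationConfig, simulate_trace
from oxykin.trace import AssayMetadata, OxygenTrace


@pytest.fixture(scope="session")
def ero1a_noisy_trace():
    """Realistic two-step cooperative trace: noise 0.5 uM, calibration
    offset, chamber chemical background."""
    cfg = SimulationConfig(params=ERO1A_PDI.params, spec=ERO1A_PDI.spec,
                           total_duration=2800.0, seed=1)
    return simulate_trace(cfg)


@pytest.fixture(scope="session")
def ero1a_clean_trace():
    """Ideal noise-free trace: exactly the fitted rate law plus electrode
    background, already on an absolute oxygen scale."""
    cfg = SimulationConfig(params=ERO1A_PDI.params, spec=ERO1A_PDI.spec,
                           total_duration=2800.0, seed=0, noise_sd=0.0,
                           calibration_offset=0.0, chemical_background_rate=0.0)
    return simulate_trace(cfg)


@pytest.fixture(scope="session")
def ero1b_noisy_trace():
    cfg = SimulationConfig(params=ERO1B_PDI.params, spec=ERO1B_PDI.spec,
                           total_duration=1900.0, seed=3)
    return simulate_trace(cfg)


@pytest.fixture(scope="session")
def erv1p_noisy_trace():
    cfg = SimulationConfig(params=ERV1P.params, spec=ERV1P.spec,
                           total_duration=2400.0, seed=5)
    return simulate_trace(cfg)


@pytest.fixture
def linear_trace():
    """250 - 0.5*t over 100 s at 10 Hz, with injection metadata."""
    t = np.arange(0.0, 100.0, 0.1)
    meta = AssayMetadata(enzyme_conc=1.0, injection_time=0.0, sample_interval=0.1)
    return OxygenTrace(times=t, oxygen=250.0 - 0.5 * t, metadata=meta)
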