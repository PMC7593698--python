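import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rpmap as rp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CL = 150.0  # default test cycle length, ms
RATE = 100.0  # analysis snapshot rate, Hz


@pytest.fixture(scope="session")
def layout64():
    return rp.make_layout(64, 2.4, "square")


@pytest.fixture(scope="session")
def layout100():
    return rp.make_layout(100, 2.4, "square")


@pytest.fixture(scope="session")
def layout249():
    return rp.make_layout(249, 2.4, "circular")


@pytest.fixture(scope="session")
def periodic_truth(layout64):
    """60 noise-free cycles of one planar wave at 150 ms cycle length."""
    sched = rp.WaveSchedule(
        (rp.WaveSegment("planar", n_cycles=60, cycle_length_ms=CL, direction_deg=30.0),)
    )
    return rp.simulate_activations(layout64, sched, seed=1)


@pytest.fixture(scope="session")
def periodic_result(periodic_truth, layout64):
    acts = rp.ActivationTimes(periodic_truth.activations, periodic_truth.duration_ms)
    return rp.analyze(acts, layout64)


@pytest.fixture(scope="session")
def paced4_truth(layout249):
    """Four sequential noise-free planar segments from the cardinal directions."""
    return rp.simulate_activations(
        layout249, rp.paced_schedule(n_cycles=15, cycle_length_ms=CL), seed=2
    )


@pytest.fixture(scope="session")
def paced4_result(paced4_truth, layout249):
    acts = rp.ActivationTimes(paced4_truth.activations, paced4_truth.duration_ms)
    return rp.analyze(acts, layout249)


@pytest.fixture(scope="session")
def random_result():
    """Spatially uncorrelated activations: no repeating conduction pattern."""
    layout = rp.make_layout(49, 2.4, "square")
    times = rp.random_activations(49, 9000.0, cycle_length_ms=CL, spread_ms=50.0, seed=3)
    return rp.analyze(rp.ActivationTimes(times, 9000.0), layout)
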