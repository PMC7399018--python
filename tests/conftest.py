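import numpy as np
import pytest

from nirsretest import (EvokedSpec, NoiseParams, PhysioParams, make_probe,
                        make_stim_schedule, simulate_session)

QUIET_PHYSIO = PhysioParams(cardiac_amp=0, resp_amp=0, mayer_amp=0,
                            drift_amp=0, background_hbo=0, background_hbr=0)
NO_NOISE = NoiseParams(intensity_noise=0, spike_rate=0, shift_prob=0)


@pytest.fixture(scope="session")
def default_probe():
    return make_probe()


@pytest.fixture(scope="session")
def compact_probe():
    return make_probe("compact")


@pytest.fixture(scope="session")
def short_schedule():
    return make_stim_schedule(5, 2.0, 10.0, 12.0, seed=1)


@pytest.fixture(scope="session")
def clean_session(compact_probe, short_schedule):
    """Noiseless evoked-only session: physiology, noise and motion off."""
    return simulate_session(
        compact_probe, short_schedule, EvokedSpec(session_amp_sd=0),
        QUIET_PHYSIO, NO_NOISE, seed=2)


@pytest.fixture(scope="session")
def isolated_session(compact_probe):
    """Noiseless session with rests long enough that successive
    hemodynamic responses do not overlap (for amplitude-recovery checks)."""
    sched = make_stim_schedule(4, 2.0, 28.0, 30.0, seed=6)
    return simulate_session(
        compact_probe, sched, EvokedSpec(session_amp_sd=0),
        QUIET_PHYSIO, NO_NOISE, seed=2)


@pytest.fixture(scope="session")
def realistic_session(compact_probe, short_schedule):
    """Defaults: physiology, background noise, motion artifacts on."""
    return simulate_session(compact_probe, short_schedule, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
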