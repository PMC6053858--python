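import numpy as np
import pytest

from smartdrt import (
    Audiogram,
    SessionConfig,
    SignalSpec,
    SimulatedListener,
    generate_cohort,
    quick_ten_protocol,
    run_session,
)

COHORT_SEED = 20


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(COHORT_SEED)


@pytest.fixture(scope="session")
def standard_cohort(cohort):
    """The 1%-false-alarm, 3-dB-sd subset used for recovery experiments."""
    return [p for p in cohort if p.psych_sd_db == 3.0 and p.false_alarm_rate == 0.01]


@pytest.fixture(scope="session")
def sloping_audiogram():
    """Steeply sloping high-frequency loss, hand-tabulated."""
    return Audiogram(
        freqs_hz=[250, 500, 1000, 2000, 4000, 8000],
        hl_db=[20, 30, 45, 70, 90, 100],
        ear_label="fixture",
    )


@pytest.fixture(scope="session")
def listener0(cohort):
    return SimulatedListener(cohort[0])


@pytest.fixture(scope="session")
def signal0(listener0):
    ten = quick_ten_protocol(
        listener0.profile.audiogram, listener0, np.random.default_rng(0)
    )
    assert ten.outcome == "dr_detected"
    return ten.signal


@pytest.fixture(scope="session")
def session0(listener0, signal0):
    """One complete standard session, shared by read-only tests."""
    cfg = SessionConfig(rng_seed=11)
    return run_session(cfg, listener0, listener0.profile.audiogram, signal0)
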