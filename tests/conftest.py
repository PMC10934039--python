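import numpy as np
import pytest

from hrv3state import (
    AutonomicProfile,
    StateParams,
    StatePlan,
    clean_rr,
    resample_tachogram,
    simulate_rr,
    sliding_trend,
)


@pytest.fixture(scope="session")
def plan() -> StatePlan:
    return StatePlan()


@pytest.fixture(scope="session")
def hf_sinusoid_rr():
    """Beat series whose R-R is exactly 1000 + 50 sin(2*pi*0.25*t) ms, 300 s."""
    beats = [0.0]
    while beats[-1] < 300.0:
        t = beats[-1]
        beats.append(t + (1000.0 + 50.0 * np.sin(2 * np.pi * 0.25 * t)) / 1000.0)
    return np.asarray(beats)


@pytest.fixture(scope="session")
def step_profile() -> AutonomicProfile:
    """Distinct per-state modulation: tests skip-rule decontamination and recovery."""
    return AutonomicProfile(
        states={
            "Rest": StateParams(mean_rr=900.0, lf_amp=25.0, hf_amp=40.0),
            "Task": StateParams(mean_rr=750.0, lf_amp=30.0, hf_amp=15.0),
            "After": StateParams(mean_rr=900.0, lf_amp=35.0, hf_amp=45.0),
        }
    )


@pytest.fixture(scope="session")
def step_profile_averages(step_profile, plan):
    """Pipeline-measured state averages of the step profile (shared by tests)."""
    from hrv3state import state_averages

    rr, _ = simulate_rr(step_profile, plan, seed=5)
    trend = sliding_trend(resample_tachogram(clean_rr(rr)))
    return state_averages(trend, plan)
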