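import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def control_trials():
    """Ten default-preset control trials, steady windows, with their lags."""
    from lfpdyn import autocorr_lag, control_preset, generate_trial, steady_window

    params = control_preset(seed=1, n_trials=10)
    windows = [steady_window(generate_trial(params, i)) for i in range(10)]
    lags = [autocorr_lag(w.samples) for w in windows]
    return windows, lags


@pytest.fixture
def small_trialset():
    """Three short trials with distinct metadata, for I/O round-trips."""
    from lfpdyn import Trial, TrialSet

    rng = np.random.default_rng(7)
    return TrialSet(tuple(
        Trial(rng.standard_normal(50), dt=1e-3, trial_id=i + 1,
              condition="control" if i < 2 else "treated", animal_id=4)
        for i in range(3)
    ))
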