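import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fatiguekit import Condition, FatigueTrial, GeneratorParams, RecoverySeries
from fatiguekit.simulate import generate_dataset

settings.register_profile(
    "fatiguekit",
    derandomize=True,
    database=None,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fatiguekit")


def make_trial(
    participant_id="P01",
    push_force=20.0,
    tool="small",
    mvc=100.0,
    met=5.0,
    ms0=58.0,
    cr10_0=8.0,
):
    return FatigueTrial(
        participant_id=participant_id,
        condition=Condition(push_force, tool),
        mvc=mvc,
        met=met,
        ms0=ms0,
        cr10_0=cr10_0,
    )


def exact_recovery_series(trial, rr, times=None):
    """A noise-free recovery trajectory for the given trial and rate."""
    t = np.arange(7.0) if times is None else np.asarray(times, dtype=float)
    ms = trial.ms0 + (trial.mvc - trial.ms0) * (1 - np.exp(-rr * t))
    cr10 = np.clip(10 - 8 * (ms - trial.ms0) / max(trial.mvc - trial.ms0, 1e-9), 0, 10)
    return RecoverySeries(trial=trial, times=t, ms=ms, cr10=cr10)


@pytest.fixture
def four_condition_trials():
    """One trial per condition combination, same participant."""
    return [
        make_trial(push_force=20.0, tool="small", met=6.9),
        make_trial(push_force=20.0, tool="large", met=7.9),
        make_trial(push_force=40.0, tool="small", met=2.5),
        make_trial(push_force=40.0, tool="large", met=2.4),
    ]


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at default parameters (17 x 4 x 7)."""
    return generate_dataset(GeneratorParams(seed=42))


@pytest.fixture(scope="session")
def noise_free_dataset():
    return generate_dataset(GeneratorParams(seed=42).noise_free())
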