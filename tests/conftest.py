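import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from bimotap.cohort import Group, Participant, Task
from bimotap.simulate import (
    CellProfile,
    GroupProfiles,
    default_profiles,
    simulate_trial,
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture()
def participant_factory():
    def make(group=Group.YA, age=None, **kwargs):
        ages = {Group.YA: 20, Group.YOA: 70, Group.OOA: 80}
        defaults = dict(
            sex="female",
            handedness="right",
            mmse=None if group is Group.YA else 28,
            group=group,
        )
        defaults.update(kwargs)
        return Participant(
            id=kwargs.get("id", f"{group.value}001"),
            age=age if age is not None else ages[group],
            **{k: v for k, v in defaults.items() if k != "id"},
        )

    return make


def make_random_profiles(rng, task):
    """A single-cell-pair profile with random but physiological parameters,
    for oracle-equivalence fuzzing."""
    def cell():
        return CellProfile(
            interval_mean=float(rng.uniform(0.25, 0.6)),
            interval_sd=float(rng.uniform(0.01, 0.1)),
            amplitude_mean=float(rng.uniform(35.0, 65.0)),
            amplitude_sd=float(rng.uniform(4.0, 9.0)),
            fatigue_slope=float(rng.uniform(-0.3, 0.2)),
        )

    return GroupProfiles(
        cells={
            (Group.YA, task, hand): cell() for hand in ("left", "right")
        },
        phase_sd={(Group.YA, task): float(rng.uniform(15.0, 45.0))},
    )


@pytest.fixture()
def random_trial_factory(participant_factory):
    def make(seed):
        rng = np.random.default_rng(seed)
        task = Task.IN_PHASE if seed % 2 == 0 else Task.ANTI_PHASE
        prof = make_random_profiles(rng, task)
        return simulate_trial(prof, participant_factory(), task, rng)

    return make
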