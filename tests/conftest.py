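import numpy as np
import pandas as pd
import pytest

from armtrial import Timepoint, default_registry

TIMEPOINTS = [tp.name for tp in Timepoint]


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_assessments(values_by_participant):
    """Long assessment frame from {pid: {outcome: [v0..v4]}} trajectories."""
    rows = []
    for pid, outcomes in values_by_participant.items():
        for outcome, traj in outcomes.items():
            for tp, v in zip(TIMEPOINTS, traj):
                rows.append(
                    {"participant_id": pid, "timepoint": tp,
                     "outcome": outcome, "value": float(v)}
                )
    return pd.DataFrame(rows)


def flat_then_jump(baseline, jump, jump_at=3):
    """Trajectory flat at baseline, stepping by ``jump`` from visit index on."""
    traj = [baseline] * 5
    for i in range(jump_at, 5):
        traj[i] = baseline + jump
    return traj


@pytest.fixture()
def make_cohort():
    return make_assessments


@pytest.fixture(scope="session")
def profile_frame():
    def build(n=6, sessions_rehab=25, sessions_therapy=25):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i + 1:02d}" for i in range(n)],
                "age": 45.0,
                "sex": "M",
                "ais_grade": "C",
                "neuro_level": "C5",
                "years_since_injury": 5.0,
                "sessions_rehab": sessions_rehab,
                "sessions_therapy": sessions_therapy,
            }
        )

    return build
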