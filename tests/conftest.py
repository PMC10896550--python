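import numpy as np
import pytest

from stuntmsm import (
    PanelDataset,
    PanelObservation,
    Trajectory,
    make_adjacent_structure,
    make_study_truth,
)

#: Observed consecutive-pair transition counts of the study cohort
#: (rows: from Normal..Severe, columns: to Normal..Severe).
OBSERVED_TRANSITION_COUNTS = np.array(
    [
        [256, 155, 77, 40],
        [175, 232, 150, 44],
        [71, 142, 249, 140],
        [37, 60, 128, 241],
    ]
)


@pytest.fixture(scope="session")
def adjacent():
    return make_adjacent_structure()


@pytest.fixture(scope="session")
def study_truth():
    return make_study_truth()


def make_dataset(children, design=None):
    """Build a PanelDataset from {child_id: [(age, state), ...]}."""
    trajs = []
    for cid, obs in children.items():
        trajs.append(
            Trajectory(
                cid,
                tuple(PanelObservation(age_months=a, state=s) for a, s in obs),
            )
        )
    return PanelDataset(tuple(trajs), design)


@pytest.fixture
def tiny_dataset():
    return make_dataset(
        {
            "a": [(2.0, 1), (5.0, 1), (9.0, 2)],
            "b": [(0.0, 3), (6.0, 4)],
            "c": [(10.0, 2)],
        }
    )
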