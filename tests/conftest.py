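import numpy as np
import pytest

from fatiguedyn.data import ParticipantDataset, TrialObservation
from fatiguedyn.task import EFFORT_FRACTIONS, TrialSpec, TrialType, rest_time


def build_dataset(
    exertion,
    ratings=None,
    baseline_rating=None,
    scale_max=100,
    participant_id="p1",
    success=None,
):
    """Assemble a ParticipantDataset from an exertion vector.

    Zero exertion marks a rest trial; work trials are labelled effort level 3
    (the middle level) since the models only consume the realised exertion.
    """
    exertion = np.asarray(exertion, dtype=float)
    if ratings is None:
        ratings = [None] * exertion.size
    if success is None:
        success = [True] * exertion.size
    obs = []
    for i, e in enumerate(exertion):
        is_rest = e == 0
        level = 0 if is_rest else 3
        spec = TrialSpec(
            index=i + 1,
            trial_type=TrialType.REST if is_rest else TrialType.WORK,
            effort_level=level,
            effort_fraction=EFFORT_FRACTIONS[level],
            reward=6,
        )
        obs.append(
            TrialObservation(
                spec=spec,
                success=True if is_rest else bool(success[i]),
                auc_raw=e / 10.0,
                auc_norm=e / 10.0,
                exertion_E=float(e),
                t_rest=rest_time(spec.trial_type),
                rating=None if ratings[i] is None else float(ratings[i]),
            )
        )
    return ParticipantDataset(
        participant_id=participant_id,
        observations=obs,
        scale_max=scale_max,
        baseline_rating=baseline_rating,
    )


@pytest.fixture
def make_dataset():
    return build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
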