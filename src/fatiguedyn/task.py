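"""Trial structure of the grip-force rating task.

The task interleaves work trials (squeeze a dynamometer to 30/39/48 % of the
participant's maximum voluntary contraction, MVC, for 3 of 5 s) with rest
trials of matched duration.  Each trial promises 6, 8 or 10 credits.  The 12
effort-by-reward combinations are counterbalanced so that each occurs equally
often in every consecutive block of 12 trials; the default task length is
120 trials (10 blocks).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TrialType",
    "TrialSpec",
    "TaskSequence",
    "generate_trial_sequence",
    "rest_time",
    "EFFORT_FRACTIONS",
    "REWARDS",
    "REST_SECONDS",
    "WORK_SECONDS",
]

#: Mapping from pie-chart effort level to fraction of MVC.  Level 0 is rest.
EFFORT_FRACTIONS: dict[int, float] = {0: 0.0, 2: 0.30, 3: 0.39, 4: 0.48}

#: Credit amounts on offer.
REWARDS: tuple[int, ...] = (6, 8, 10)

#: Effective rest durations (seconds) entering the recoverable-fatigue decay.
REST_SECONDS: float = 7.5
WORK_SECONDS: float = 2.5

_EXPERIMENTS = ("exp1", "exp2", "exp3")


class TrialType(str, enum.Enum):
    WORK = "work"
    REST = "rest"


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: what is cued, not what the participant did."""

    index: int
    trial_type: TrialType
    effort_level: int
    effort_fraction: float
    reward: int
    reward_shown_before: bool = True

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"trial index must be >= 1, got {self.index}")
        if self.effort_level not in EFFORT_FRACTIONS:
            raise ValueError(f"effort_level must be one of {sorted(EFFORT_FRACTIONS)}")
        if self.reward not in REWARDS:
            raise ValueError(f"reward must be one of {REWARDS}, got {self.reward}")
        expected = EFFORT_FRACTIONS[self.effort_level]
        if abs(self.effort_fraction - expected) > 1e-12:
            raise ValueError(
                f"effort_fraction {self.effort_fraction} inconsistent with level "
                f"{self.effort_level} (expected {expected})"
            )
        is_rest = self.trial_type == TrialType.REST
        if is_rest != (self.effort_level == 0):
            raise ValueError("rest trials must have effort_level 0 and vice versa")


@dataclass
class TaskSequence:
    """An ordered, counterbalanced sequence of trials."""

    trials: list[TrialSpec]
    seed: int
    experiment_id: str = "exp1"

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "trial_type": [t.trial_type.value for t in self.trials],
                "effort_level": [t.effort_level for t in self.trials],
                "effort_fraction": [t.effort_fraction for t in self.trials],
                "reward": [t.reward for t in self.trials],
                "reward_shown_before": [t.reward_shown_before for t in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = -1,
                   experiment_id: str = "exp1") -> "TaskSequence":
        trials = [
            TrialSpec(
                index=int(row.trial),
                trial_type=TrialType(row.trial_type),
                effort_level=int(row.effort_level),
                effort_fraction=float(row.effort_fraction),
                reward=int(row.reward),
                reward_shown_before=bool(row.reward_shown_before),
            )
            for row in frame.itertuples()
        ]
        return cls(trials=trials, seed=seed, experiment_id=experiment_id)

    @classmethod
    def from_csv(cls, path, seed: int = -1, experiment_id: str = "exp1") -> "TaskSequence":
        return cls.from_frame(pd.read_csv(path), seed=seed, experiment_id=experiment_id)


def rest_time(trial_type: TrialType | str) -> float:
    """Effective rest duration feeding the recoverable-fatigue decay.

    Rest trials allow 7.5 s of recovery, work trials 2.5 s (the non-exertion
    portion of the trial).
    """
    trial_type = TrialType(trial_type)
    return REST_SECONDS if trial_type == TrialType.REST else WORK_SECONDS


def generate_trial_sequence(
    n_trials: int = 120, seed: int = 0, experiment_id: str = "exp1"
) -> TaskSequence:
    """Generate a counterbalanced pseudo-random trial sequence.

    The 12 effort-by-reward combinations are shuffled independently within
    each consecutive block of 12 trials, which guarantees that every
    combination occurs exactly ``n_trials / 12`` times and is distributed
    evenly across the task.  The output is a pure function of the arguments.

    Parameters
    ----------
    n_trials : int
        Task length; must be a positive multiple of 12.
    seed : int
        Seed for the block shuffles.
    experiment_id : {"exp1", "exp2", "exp3"}
        In "exp3" the reward is only revealed after exertion
        (``reward_shown_before=False`` on every trial).
    """
    if experiment_id not in _EXPERIMENTS:
        raise ValueError(f"experiment_id must be one of {_EXPERIMENTS}")
    if n_trials <= 0 or n_trials % 12 != 0:
        raise ValueError(
            f"n_trials must be a positive multiple of 12 (one per effort x reward "
            f"combination), got {n_trials}"
        )
    rng = np.random.default_rng(seed)
    combos = [(lvl, rwd) for lvl in sorted(EFFORT_FRACTIONS) for rwd in REWARDS]
    shown = experiment_id != "exp3"

    trials: list[TrialSpec] = []
    for block in range(n_trials // 12):
        order = rng.permutation(len(combos))
        for pos, j in enumerate(order):
            level, reward = combos[j]
            trials.append(
                TrialSpec(
                    index=block * 12 + pos + 1,
                    trial_type=TrialType.REST if level == 0 else TrialType.WORK,
                    effort_level=level,
                    effort_fraction=EFFORT_FRACTIONS[level],
                    reward=reward,
                    reward_shown_before=shown,
                )
            )
    return TaskSequence(trials=trials, seed=seed, experiment_id=experiment_id)
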