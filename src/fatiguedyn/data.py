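"""Shared behavioural-data containers and the long-format trial-table schema.

The long-format trial table is the interchange format between modules, one
row per executed trial:

``participant,trial,trial_type,effort_level,reward,success,auc_norm,
exertion_E,t_rest,rating,baseline_rating,scale_max,experiment_id``

``rating`` may be empty (missing).  ``baseline_rating`` is empty when no
baseline was collected (effort-rating experiments).  ``exertion_E`` is the
participant-normalised force AUC scaled by 10, so it lies in [0, 10].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .task import TrialSpec, TrialType, EFFORT_FRACTIONS, rest_time

__all__ = ["TrialObservation", "ParticipantDataset", "read_trial_table",
           "write_trial_table", "TRIAL_TABLE_COLUMNS"]

TRIAL_TABLE_COLUMNS = [
    "participant", "trial", "trial_type", "effort_level", "reward", "success",
    "auc_norm", "exertion_E", "t_rest", "rating",
]
_META_COLUMNS = ["baseline_rating", "scale_max", "experiment_id"]


@dataclass
class TrialObservation:
    """One executed trial: the planned spec plus what actually happened."""

    spec: TrialSpec
    success: bool
    auc_raw: float
    auc_norm: float
    exertion_E: float
    t_rest: float
    rating: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 - 1e-9 <= self.auc_norm <= 1.0 + 1e-9):
            raise ValueError(f"auc_norm must lie in [0, 1], got {self.auc_norm}")
        if abs(self.exertion_E - self.auc_norm * 10.0) > 1e-6:
            raise ValueError("exertion_E must equal auc_norm * 10")
        if self.spec.trial_type == TrialType.REST:
            if self.exertion_E != 0 or not self.success:
                raise ValueError("rest trials must have zero exertion and success=True")


@dataclass
class ParticipantDataset:
    """All trials of one participant plus rating-scale metadata.

    ``truth`` holds the generating model and parameters for synthetic
    participants (``None`` for real data).
    """

    participant_id: str
    observations: list[TrialObservation]
    scale_max: int
    baseline_rating: Optional[int] = None
    experiment_id: str = "exp1"
    mvc: float = 1.0
    truth: Optional[dict] = None
    #: False for uncensored diagnostic simulations, where ratings are the raw
    #: model output and may exceed the nominal scale.
    censored: bool = True

    def __post_init__(self) -> None:
        idx = [o.spec.index for o in self.observations]
        if idx != sorted(idx):
            raise ValueError("observations must be ordered by trial index")
        for o in self.observations:
            if o.rating is None:
                continue
            if o.rating < 0 or (self.censored and o.rating > self.scale_max):
                raise ValueError(
                    f"rating {o.rating} outside [0, {self.scale_max}] "
                    f"for participant {self.participant_id}"
                )

    def __len__(self) -> int:
        return len(self.observations)

    # -- array views used by the fitting code -------------------------------
    @property
    def exertion(self) -> np.ndarray:
        return np.array([o.exertion_E for o in self.observations], dtype=float)

    @property
    def t_rest(self) -> np.ndarray:
        return np.array([o.t_rest for o in self.observations], dtype=float)

    @property
    def is_work(self) -> np.ndarray:
        return np.array(
            [o.spec.trial_type == TrialType.WORK for o in self.observations], dtype=bool
        )

    @property
    def success(self) -> np.ndarray:
        return np.array([o.success for o in self.observations], dtype=bool)

    @property
    def ratings(self) -> np.ndarray:
        """Ratings as float with NaN for missing."""
        return np.array(
            [math.nan if o.rating is None else float(o.rating) for o in self.observations],
            dtype=float,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "participant": self.participant_id,
                "trial": [o.spec.index for o in self.observations],
                "trial_type": [o.spec.trial_type.value for o in self.observations],
                "effort_level": [o.spec.effort_level for o in self.observations],
                "reward": [o.spec.reward for o in self.observations],
                "success": [o.success for o in self.observations],
                "auc_norm": [o.auc_norm for o in self.observations],
                "exertion_E": [o.exertion_E for o in self.observations],
                "t_rest": [o.t_rest for o in self.observations],
                "rating": self.ratings,
                "baseline_rating": (
                    np.nan if self.baseline_rating is None else self.baseline_rating
                ),
                "scale_max": self.scale_max,
                "experiment_id": self.experiment_id,
            }
        )
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ParticipantDataset":
        frame = frame.sort_values("trial")
        pid = str(frame["participant"].iloc[0])
        scale_max = int(frame["scale_max"].iloc[0]) if "scale_max" in frame else 100
        baseline = None
        if "baseline_rating" in frame:
            b = frame["baseline_rating"].iloc[0]
            baseline = None if pd.isna(b) else int(b)
        experiment_id = (
            str(frame["experiment_id"].iloc[0]) if "experiment_id" in frame else "exp1"
        )
        shown = experiment_id != "exp3"
        obs = []
        for row in frame.itertuples():
            level = int(row.effort_level)
            spec = TrialSpec(
                index=int(row.trial),
                trial_type=TrialType(row.trial_type),
                effort_level=level,
                effort_fraction=EFFORT_FRACTIONS[level],
                reward=int(row.reward),
                reward_shown_before=shown,
            )
            rating = None if pd.isna(row.rating) else float(row.rating)
            auc_norm = float(row.auc_norm)
            obs.append(
                TrialObservation(
                    spec=spec,
                    success=bool(row.success),
                    auc_raw=auc_norm,  # raw AUC is not round-tripped
                    auc_norm=auc_norm,
                    exertion_E=float(row.exertion_E),
                    t_rest=float(row.t_rest),
                    rating=rating,
                )
            )
        return cls(
            participant_id=pid,
            observations=obs,
            scale_max=scale_max,
            baseline_rating=baseline,
            experiment_id=experiment_id,
        )


def write_trial_table(datasets: list[ParticipantDataset], path) -> None:
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(path, index=False)


def read_trial_table(path) -> list[ParticipantDataset]:
    """Read a long-format trial table into per-participant datasets.

    Raises
    ------
    ValueError
        If a required column is missing (named in the message).
    """
    frame = pd.read_csv(path)
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing required columns: {missing}")
    return [
        ParticipantDataset.from_frame(group)
        for _, group in frame.groupby("participant", sort=True)
    ]
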