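"""Grip-force trace processing.

Converts raw dynamometer traces into the per-trial exertion quantity the
fatigue models consume: the area under the force-time curve (AUC), normalised
by each participant's maximum AUC and scaled by 10, and the success judgement
(force at or above the target for a cumulative 3 s within the 5-s window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ForceTrace", "compute_auc", "normalize_auc", "judge_success",
           "SUCCESS_SECONDS", "WINDOW_SECONDS"]

#: Cumulative time at/above target required for a successful squeeze.
SUCCESS_SECONDS: float = 3.0
#: Duration of the exertion window.
WINDOW_SECONDS: float = 5.0


@dataclass
class ForceTrace:
    """A force-time trace for one trial.

    ``force`` is in fraction-of-MVC units so traces are comparable across
    participants; times are 0-based seconds spanning ``[0, window_duration]``.
    """

    times: np.ndarray
    force: np.ndarray
    window_duration: float = WINDOW_SECONDS

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.times.shape != self.force.shape or self.times.ndim != 1:
            raise ValueError("times and force must be 1-D arrays of equal length")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.window_duration + 1e-9):
            raise ValueError("times must lie within [0, window_duration]")
        if np.any(self.force < 0):
            raise ValueError("force values must be non-negative")


def compute_auc(trace: ForceTrace) -> float:
    """Trapezoidal area under the force-time curve, in force x seconds."""
    if trace.times.size < 2:
        raise ValueError("need at least 2 samples to integrate a force trace")
    return float(np.trapezoid(trace.force, trace.times))


def normalize_auc(auc_values) -> np.ndarray:
    """Divide a participant's per-trial AUCs by that participant's maximum.

    The maximum is taken over all of the participant's trials (including
    failed ones), so the largest value maps to exactly 1.0.
    """
    values = np.asarray(auc_values, dtype=float)
    if values.size == 0:
        raise ValueError("no AUC values to normalise")
    if np.any(values < 0):
        raise ValueError("AUC values must be non-negative")
    peak = values.max()
    if peak <= 0:
        raise ValueError("all AUC values are zero; cannot normalise this participant")
    return values / peak


def judge_success(trace: ForceTrace, required_fraction: float) -> bool:
    """Was force held at/above the target for a cumulative 3 s?

    Time at target is accumulated over sampling intervals whose two endpoint
    samples are both at or above ``required_fraction`` (ties count as
    reaching the target).  Rest trials (``required_fraction == 0``) always
    succeed.
    """
    if required_fraction < 0:
        raise ValueError("required_fraction must be >= 0")
    if required_fraction == 0:
        return True
    above = trace.force >= required_fraction
    if trace.times.size < 2:
        return False
    dt = np.diff(trace.times)
    both = above[:-1] & above[1:]
    return float(np.sum(dt[both])) >= SUCCESS_SECONDS
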