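"""Latent fatigue dynamics and rating readouts.

The model decomposes momentary fatigue F into a fixed baseline plus two
latent components updated trial by trial::

    F(t) = F_start + RF(t) + UF(t)

Recoverable fatigue RF rises with the force exerted on a trial
(``alpha * E``) and falls with the time rested (``delta * T_rest``), clamped
at zero; unrecoverable fatigue UF only accumulates (``theta * E``).  E is the
participant-normalised force AUC scaled by 10, T_rest is 7.5 s on rest trials
and 2.5 s on work trials.

Two readouts map the latent state to a rating prediction:

* fatigue readout — the prediction is F itself (0-100 scale);
* effort readout — perceived effort on work trials is ``(gamma + F) * E``
  (multiplicative family) or ``gamma * E + F`` (additive family) and 0 on
  rest trials (0-20 scale).

The model family spans nested restrictions of the full model, from a static
null model (effort readout only, ``gamma`` alone) to the full
``alpha, delta, theta`` dynamics.  One-parameter recoverable variants tie the
recovery rate to the accumulation rate (``delta = alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "FatigueParams",
    "FatigueState",
    "ModelSpec",
    "Trajectory",
    "get_model",
    "model_family",
    "update_recoverable",
    "update_unrecoverable",
    "predict_effort",
    "trajectory",
    "resolve_baseline",
    "EFFORT_MODEL_IDS",
    "FATIGUE_MODEL_IDS",
]

_PARAM_NAMES = ("alpha", "delta", "theta", "gamma")

# Base model id -> (dynamic free parameters, delta tied to alpha?)
_BASE_FAMILY: dict[str, tuple[tuple[str, ...], bool]] = {
    "null": ((), False),
    "uf": (("theta",), False),
    "rf": (("alpha", "delta"), False),
    "rf1": (("alpha",), True),
    "uf_rf1": (("theta", "alpha"), True),
    "full": (("alpha", "delta", "theta"), False),
}

#: Effort-rating model family (multiplicative; append ``_add`` for additive).
EFFORT_MODEL_IDS = ("null", "uf", "rf", "rf1", "uf_rf1", "full")
#: Fatigue-rating model family (no static effort weight, no null model).
FATIGUE_MODEL_IDS = ("uf", "rf", "rf1", "uf_rf1", "full")


@dataclass(frozen=True)
class FatigueParams:
    """Subject-level sensitivities; all constrained non-negative.

    alpha : rise in recoverable fatigue per unit exertion
    delta : fall in recoverable fatigue per second rested
    theta : rise in unrecoverable fatigue per unit exertion
    gamma : static effort weight (effort-readout models only)
    """

    alpha: float = 0.0
    delta: float = 0.0
    theta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _PARAM_NAMES}


@dataclass(frozen=True)
class FatigueState:
    """Latent state after one trial's update."""

    RF: float
    UF: float
    F: float
    F_start: float


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free and how the prediction is read out."""

    model_id: str
    readout: str  # "effort" | "fatigue"
    combination: str = "multiplicative"  # "multiplicative" | "additive"
    free_params: tuple[str, ...] = ()
    tie_delta: bool = False

    def __post_init__(self) -> None:
        if self.readout not in ("effort", "fatigue"):
            raise ValueError("readout must be 'effort' or 'fatigue'")
        if self.combination not in ("multiplicative", "additive"):
            raise ValueError("combination must be 'multiplicative' or 'additive'")
        if self.readout == "effort" and "gamma" not in self.free_params:
            raise ValueError("effort-readout models must fit gamma")
        if self.readout == "fatigue" and "gamma" in self.free_params:
            raise ValueError("fatigue-readout models have no gamma")

    @property
    def n_params(self) -> int:
        return len(self.free_params)

    def effective(self, params: FatigueParams) -> tuple[float, float, float, float]:
        """(alpha, delta, theta, gamma) with non-free parameters held at 0
        and the one-parameter tie (delta = alpha) applied."""
        alpha = params.alpha if "alpha" in self.free_params else 0.0
        theta = params.theta if "theta" in self.free_params else 0.0
        gamma = params.gamma if "gamma" in self.free_params else 0.0
        if self.tie_delta:
            delta = alpha
        else:
            delta = params.delta if "delta" in self.free_params else 0.0
        return alpha, delta, theta, gamma


def get_model(model_id: str, readout: str) -> ModelSpec:
    """Resolve a string id (e.g. ``"full"``, ``"uf_rf1_add"``) to a ModelSpec."""
    combination = "multiplicative"
    base = model_id
    if model_id.endswith("_add"):
        combination = "additive"
        base = model_id[: -len("_add")]
    if base not in _BASE_FAMILY:
        raise ValueError(f"unknown model id {model_id!r}; bases are {sorted(_BASE_FAMILY)}")
    if combination == "additive" and readout != "effort":
        raise ValueError("additive variants exist only for the effort readout")
    if base == "null" and readout != "effort":
        raise ValueError("the null model exists only for the effort readout")
    dyn, tie = _BASE_FAMILY[base]
    free = dyn + (("gamma",) if readout == "effort" else ())
    return ModelSpec(
        model_id=model_id,
        readout=readout,
        combination=combination,
        free_params=free,
        tie_delta=tie,
    )


def model_family(readout: str, combination: str = "multiplicative") -> list[ModelSpec]:
    """The candidate set compared for one readout."""
    if readout == "effort":
        suffix = "_add" if combination == "additive" else ""
        return [get_model(mid + suffix, "effort") for mid in EFFORT_MODEL_IDS]
    return [get_model(mid, "fatigue") for mid in FATIGUE_MODEL_IDS]


# ---------------------------------------------------------------------------
# single-trial updates


def update_recoverable(
    RF_prev: float, exertion_E: float, t_rest: float, alpha: float, delta: float
) -> float:
    """One trial's recoverable-fatigue update, clamped at zero.

    On every trial both the exertion increment (``alpha * E``) and the rest
    decrement (``delta * t_rest``) apply; work trials carry t_rest = 2.5 s,
    rest trials 7.5 s.
    """
    return max(0.0, RF_prev + alpha * exertion_E - delta * t_rest)


def update_unrecoverable(UF_prev: float, exertion_E: float, theta: float) -> float:
    """One trial's unrecoverable-fatigue accumulation (never decreases)."""
    return UF_prev + theta * exertion_E


def predict_effort(
    gamma: float,
    F_t: float,
    exertion_E: float,
    trial_type,
    combination: str = "multiplicative",
) -> float:
    """Perceived effort on one trial; defined as 0 on rest trials."""
    from .task import TrialType

    if TrialType(trial_type) == TrialType.REST:
        return 0.0
    if combination == "multiplicative":
        return (gamma + F_t) * exertion_E
    if combination == "additive":
        return gamma * exertion_E + F_t
    raise ValueError(f"unknown combination {combination!r}")


def resolve_baseline(baseline_rating: Optional[float]) -> float:
    """Baseline fatigue F_start: the pre-task rating, or 0.01 when that
    rating is zero or was never collected."""
    if baseline_rating is None or baseline_rating == 0:
        return 0.01
    if baseline_rating < 0:
        raise ValueError("baseline rating cannot be negative")
    return float(baseline_rating)


# ---------------------------------------------------------------------------
# whole-task trajectory


def _predict_arrays(
    exertion: np.ndarray,
    t_rest: np.ndarray,
    is_work: np.ndarray,
    alpha: float,
    delta: float,
    theta: float,
    gamma: float,
    f_start: float,
    readout: str,
    combination: str,
    state_timing: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised trajectory core; returns (RF, UF, F, predicted).

    The clamped recoverable recursion RF_t = max(0, RF_{t-1} + g_t) with
    g_t = alpha*E_t - delta*T_t has the closed form
    RF_t = C_t - min(0, min_{s<=t} C_s) where C is the cumulative sum of g,
    which allows a loop-free evaluation.
    """
    UF = np.cumsum(theta * exertion)
    g = alpha * exertion - delta * t_rest
    C = np.cumsum(g)
    RF = C - np.minimum.accumulate(np.minimum(C, 0.0))
    F = f_start + RF + UF
    if state_timing == "post":
        F_used = F
    elif state_timing == "pre":
        F_used = np.concatenate(([f_start], F[:-1]))
    else:
        raise ValueError("state_timing must be 'post' or 'pre'")
    if readout == "fatigue":
        predicted = F_used.copy()
    else:
        if combination == "multiplicative":
            work_pred = (gamma + F_used) * exertion
        else:
            work_pred = gamma * exertion + F_used
        predicted = np.where(is_work, work_pred, 0.0)
    return RF, UF, F, predicted


@dataclass
class Trajectory:
    """Per-trial latent states and rating predictions for one participant."""

    rf: np.ndarray
    uf: np.ndarray
    f: np.ndarray
    predicted: np.ndarray
    f_start: float

    def states(self) -> Iterator[tuple[FatigueState, float]]:
        for rf, uf, f, p in zip(self.rf, self.uf, self.f, self.predicted):
            yield FatigueState(RF=float(rf), UF=float(uf), F=float(f),
                               F_start=self.f_start), float(p)

    def to_frame(self, observed: Optional[np.ndarray] = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "trial": np.arange(1, len(self.rf) + 1),
                "RF": self.rf,
                "UF": self.uf,
                "F": self.f,
                "predicted": self.predicted,
            }
        )
        if observed is not None:
            frame["observed"] = np.asarray(observed, dtype=float)
        return frame


def trajectory(
    model: ModelSpec,
    params: FatigueParams,
    exertion,
    t_rest,
    is_work,
    f_start: float,
    state_timing: str = "post",
) -> Trajectory:
    """Run the latent dynamics over an ordered trial sequence.

    RF and UF start at 0 and are updated on every trial from that trial's
    exertion and rest time; the prediction for trial t uses, by default, the
    state after trial t's update (``state_timing="post"``) because ratings
    are collected after exertion.

    Parameters not free in ``model`` are held at zero; for the one-parameter
    recoverable models the rest decrement is tied to ``alpha``.
    """
    if f_start <= 0:
        raise ValueError("f_start must be > 0 (use resolve_baseline)")
    exertion = np.asarray(exertion, dtype=float)
    t_rest_arr = np.asarray(t_rest, dtype=float)
    is_work_arr = np.asarray(is_work, dtype=bool)
    if not (exertion.shape == t_rest_arr.shape == is_work_arr.shape):
        raise ValueError("exertion, t_rest and is_work must have equal length")
    alpha, delta, theta, gamma = model.effective(params)
    rf, uf, f, pred = _predict_arrays(
        exertion, t_rest_arr, is_work_arr, alpha, delta, theta, gamma,
        float(f_start), model.readout, model.combination, state_timing,
    )
    return Trajectory(rf=rf, uf=uf, f=f, predicted=pred, f_start=float(f_start))
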