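"""Per-participant model fitting by multi-start Nelder-Mead RSS minimisation.

Each candidate model is fitted to one participant's ratings by minimising the
sum of squared residuals between observed and predicted ratings.  The
simplex search is restarted from a full factorial grid of initial values
(six per free parameter, equally spaced on [0, 1] by default) and the lowest
RSS solution is kept.  Non-negativity of parameters is enforced by a large
finite penalty inside the objective.  Fits are scored with
``AIC = n * ln(RSS / n) + 2 * d`` and with the squared Pearson correlation
between observed and predicted ratings.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .data import ParticipantDataset
from .models import (
    FatigueParams,
    ModelSpec,
    Trajectory,
    get_model,
    resolve_baseline,
    trajectory,
)

__all__ = [
    "FatigueRatingModel",
    "FitResult",
    "aic",
    "r_squared",
    "initialisation_grid",
    "rss_objective",
    "fit_participant",
    "fit_cohort",
]

logger = logging.getLogger(__name__)

#: Objective value returned for any infeasible (negative) parameter vector.
NEGATIVE_PARAM_PENALTY = 1e12


def aic(rss: float, n_obs: int, n_params: int, *, rss_floor: Optional[float] = None) -> float:
    """Akaike Information Criterion from a residual sum of squares.

    ``AIC = n * ln(RSS / n) + 2 * d``.  A zero (or negative) RSS is
    log-degenerate: it raises unless ``rss_floor`` is given, in which case the
    RSS is floored at that value with a warning.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    if rss <= 0:
        if rss_floor is None:
            raise ValueError(
                f"AIC undefined for RSS <= 0 (got {rss}); pass rss_floor to floor it"
            )
        warnings.warn(
            f"RSS {rss} <= 0; flooring at {rss_floor} for AIC", RuntimeWarning,
            stacklevel=2,
        )
        rss = rss_floor
    return n_obs * np.log(rss / n_obs) + 2 * n_params


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted ratings.

    Returns NaN (missing) when either series has zero variance.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-D arrays of equal length")
    if observed.size < 3:
        raise ValueError("need at least 3 paired values for a correlation")
    if np.std(observed) == 0 or np.std(predicted) == 0:
        warnings.warn("zero variance: R^2 undefined, returning NaN", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r * r)


def initialisation_grid(
    free_params: Sequence[str], n_per_param: int = 6, lo: float = 0.0, hi: float = 1.0
) -> np.ndarray:
    """Full factorial grid of optimizer starting points.

    Returns an array of shape ``(n_per_param ** d, d)`` whose columns follow
    the order of ``free_params``; values are equally spaced on [lo, hi]
    inclusive of the endpoints.
    """
    if n_per_param < 2:
        raise ValueError("n_per_param must be >= 2")
    d = len(free_params)
    axis = np.linspace(lo, hi, n_per_param)
    if d == 0:
        return np.zeros((1, 0))
    return np.array(list(itertools.product(axis, repeat=d)))


def _vector_to_params(x: np.ndarray, free_params: Sequence[str]) -> FatigueParams:
    return FatigueParams(**{name: float(v) for name, v in zip(free_params, x)})


def _residual_mask(dataset: ParticipantDataset, include_failed: bool) -> np.ndarray:
    mask = ~np.isnan(dataset.ratings)
    if not include_failed:
        mask &= dataset.success
    return mask


def rss_objective(
    model: ModelSpec,
    params: FatigueParams | np.ndarray,
    dataset: ParticipantDataset,
    state_timing: str = "post",
    include_failed: bool = True,
) -> float:
    """Sum of squared residuals over the participant's rated trials.

    Negative parameter values return a large finite penalty rather than
    raising, so an unconstrained simplex search stays inside the feasible
    region.
    """
    if isinstance(params, FatigueParams):
        x = np.array([getattr(params, p) for p in model.free_params])
    else:
        x = np.asarray(params, dtype=float)
    mask = _residual_mask(dataset, include_failed)
    if not mask.any():
        raise ValueError("participant has no rated trials to fit")
    return _rss_raw(
        x, model, dataset.exertion, dataset.t_rest, dataset.is_work,
        dataset.ratings, mask, resolve_baseline(dataset.baseline_rating),
        state_timing,
    )


def _rss_raw(
    x: np.ndarray,
    model: ModelSpec,
    exertion: np.ndarray,
    t_rest: np.ndarray,
    is_work: np.ndarray,
    ratings: np.ndarray,
    mask: np.ndarray,
    f_start: float,
    state_timing: str,
) -> float:
    if np.any(x < 0):
        return NEGATIVE_PARAM_PENALTY
    params = _vector_to_params(x, model.free_params)
    traj = trajectory(model, params, exertion, t_rest, is_work, f_start, state_timing)
    resid = ratings[mask] - traj.predicted[mask]
    return float(resid @ resid)


@dataclass
class FitResult:
    """One participant x model optimum."""

    participant_id: str
    model_id: str
    params: FatigueParams
    rss: float
    n_obs: int
    n_params: int
    aic: float
    r_squared: float
    predicted: np.ndarray
    trajectory: Trajectory
    n_starts: int
    converged_fraction: float

    def to_row(self) -> dict:
        row = {
            "participant": self.participant_id,
            "model_id": self.model_id,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "aic": self.aic,
            "r_squared": self.r_squared,
            "n_starts": self.n_starts,
            "converged_fraction": self.converged_fraction,
        }
        row.update(self.params.as_dict())
        return row


class FatigueRatingModel(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for one candidate fatigue model.

    ``fit`` takes a :class:`~fatiguedyn.data.ParticipantDataset` (or a
    long-format trial-table DataFrame plus a rating vector ``y``) and finds
    the non-negative parameters minimising the residual sum of squares via
    Nelder-Mead restarted from a factorial grid of initial values.

    Parameters
    ----------
    model_id : str
        ``"null" | "uf" | "rf" | "rf1" | "uf_rf1" | "full"`` with an optional
        ``"_add"`` suffix for the additive effort-readout variants.
    readout : {"fatigue", "effort"}
        Whether ratings are of fatigue (0-100) or perceived effort (0-20).
    baseline_rating : int or None
        Pre-task fatigue rating; ``None`` or 0 resolves to 0.01.  Ignored
        when fitting a ParticipantDataset, which carries its own baseline.
    state_timing : {"post", "pre"}
        Whether the prediction for trial t uses the latent state after
        (default) or before that trial's update.
    include_failed : bool
        Keep failed work trials in the residuals (their exerted force always
        drives the latent dynamics).
    n_starts_per_param, init_lo, init_hi
        Factorial initialisation grid: ``n_starts_per_param ** d`` starts
        equally spaced on [init_lo, init_hi].
    xatol, fatol, maxiter_factor
        Simplex tolerances and the per-start iteration cap
        ``maxiter_factor * d``.
    n_polish : int
        Number of additional simplex restarts from the incumbent optimum
        (useful for noiseless data where a tight optimum is wanted).

    Attributes
    ----------
    params_ : FatigueParams
        Best-fitting parameters (non-negative).
    rss_, aic_, r_squared_ : float
        Fit statistics at the optimum.
    predicted_ : ndarray
        Predicted rating per trial.
    n_starts_, converged_fraction_ : grid-search diagnostics.
    """

    def __init__(
        self,
        model_id: str = "full",
        readout: str = "fatigue",
        baseline_rating: Optional[int] = None,
        state_timing: str = "post",
        include_failed: bool = True,
        n_starts_per_param: int = 6,
        init_lo: float = 0.0,
        init_hi: float = 1.0,
        xatol: float = 1e-4,
        fatol: float = 1e-4,
        maxiter_factor: int = 200,
        n_polish: int = 0,
        rss_floor: float = 1e-12,
    ):
        self.model_id = model_id
        self.readout = readout
        self.baseline_rating = baseline_rating
        self.state_timing = state_timing
        self.include_failed = include_failed
        self.n_starts_per_param = n_starts_per_param
        self.init_lo = init_lo
        self.init_hi = init_hi
        self.xatol = xatol
        self.fatol = fatol
        self.maxiter_factor = maxiter_factor
        self.n_polish = n_polish
        self.rss_floor = rss_floor

    # -- helpers ------------------------------------------------------------
    def _resolve_inputs(self, X, y):
        if isinstance(X, ParticipantDataset):
            ds = X
            return (
                ds.participant_id,
                ds.exertion,
                ds.t_rest,
                ds.is_work,
                ds.ratings if y is None else np.asarray(y, dtype=float),
                ds.success,
                resolve_baseline(ds.baseline_rating),
            )
        frame = pd.DataFrame(X)
        for col in ("exertion_E", "t_rest", "trial_type"):
            if col not in frame.columns:
                raise ValueError(f"trial table is missing required column {col!r}")
        is_work = frame["trial_type"].astype(str).to_numpy() == "work"
        if y is not None:
            ratings = np.asarray(y, dtype=float)
        elif "rating" in frame.columns:
            ratings = frame["rating"].to_numpy(dtype=float)
        else:
            ratings = np.full(len(frame), np.nan)
        success = (
            frame["success"].to_numpy(dtype=bool)
            if "success" in frame.columns
            else np.ones(len(frame), dtype=bool)
        )
        pid = str(frame["participant"].iloc[0]) if "participant" in frame.columns else ""
        return (
            pid,
            frame["exertion_E"].to_numpy(dtype=float),
            frame["t_rest"].to_numpy(dtype=float),
            is_work,
            ratings,
            success,
            resolve_baseline(self.baseline_rating),
        )

    def fit(self, X, y=None):
        """Fit the model to one participant's ratings.

        X may be a ParticipantDataset or a trial-table DataFrame; y may
        override the ratings.
        """
        spec = get_model(self.model_id, self.readout)
        pid, exertion, t_rest, is_work, ratings, success, f_start = (
            self._resolve_inputs(X, y)
        )
        mask = ~np.isnan(ratings)
        if not self.include_failed:
            mask &= success
        if not mask.any():
            raise ValueError("no rated trials to fit")

        def objective(x: np.ndarray) -> float:
            return _rss_raw(
                x, spec, exertion, t_rest, is_work, ratings, mask, f_start,
                self.state_timing,
            )

        d = spec.n_params
        starts = initialisation_grid(
            spec.free_params, self.n_starts_per_param, self.init_lo, self.init_hi
        )
        best_x, best_f = starts[0], objective(starts[0])
        n_converged = 0
        n_run = 0
        if d > 0:
            options = {
                "xatol": self.xatol,
                "fatol": self.fatol,
                "maxiter": self.maxiter_factor * d,
                "maxfev": self.maxiter_factor * d,
            }
            for x0 in starts:
                try:
                    res = optimize.minimize(
                        objective, x0, method="Nelder-Mead", options=options
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    logger.warning("start %s failed: %s", x0, exc)
                    continue
                n_run += 1
                n_converged += bool(res.success)
                if res.fun < best_f:
                    best_x, best_f = res.x, res.fun
            if n_run == 0:
                raise RuntimeError(
                    f"all {len(starts)} optimizer starts failed for model "
                    f"{self.model_id}, participant {pid}"
                )
            for _ in range(self.n_polish):
                res = optimize.minimize(
                    objective, best_x, method="Nelder-Mead", options=options
                )
                if res.fun < best_f:
                    best_x, best_f = res.x, res.fun
        else:  # no free parameters: nothing to optimise
            n_run = 1
            n_converged = 1

        best_x = np.maximum(best_x, 0.0)  # guard against -0.0 and roundoff
        self.participant_id_ = pid
        self.model_spec_ = spec
        self.params_ = _vector_to_params(best_x, spec.free_params)
        self.f_start_ = f_start
        traj = trajectory(
            spec, self.params_, exertion, t_rest, is_work, f_start, self.state_timing
        )
        self.trajectory_ = traj
        self.predicted_ = traj.predicted
        resid = ratings[mask] - traj.predicted[mask]
        self.rss_ = float(resid @ resid)
        self.n_obs_ = int(mask.sum())
        self.n_params_ = d
        self.aic_ = aic(self.rss_, self.n_obs_, d, rss_floor=self.rss_floor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.r_squared_ = (
                r_squared(ratings[mask], traj.predicted[mask])
                if mask.sum() >= 3
                else float("nan")
            )
        self.n_starts_ = len(starts)
        self.converged_fraction_ = n_converged / max(n_run, 1)
        return self

    def predict(self, X):
        """Predicted ratings for a trial table using the fitted parameters."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        _, exertion, t_rest, is_work, _, _, f_start = self._resolve_inputs(X, None)
        if isinstance(X, ParticipantDataset):
            f_start = resolve_baseline(X.baseline_rating)
        traj = trajectory(
            self.model_spec_, self.params_, exertion, t_rest, is_work,
            f_start, self.state_timing,
        )
        return traj.predicted

    def result_(self) -> FitResult:
        """Package the fitted attributes as a FitResult record."""
        return FitResult(
            participant_id=self.participant_id_,
            model_id=self.model_id,
            params=self.params_,
            rss=self.rss_,
            n_obs=self.n_obs_,
            n_params=self.n_params_,
            aic=self.aic_,
            r_squared=self.r_squared_,
            predicted=self.predicted_,
            trajectory=self.trajectory_,
            n_starts=self.n_starts_,
            converged_fraction=self.converged_fraction_,
        )


def fit_participant(
    model_id: str,
    dataset: ParticipantDataset,
    readout: str = "fatigue",
    **estimator_kwargs,
) -> FitResult:
    """Fit one candidate model to one participant (functional wrapper)."""
    est = FatigueRatingModel(model_id=model_id, readout=readout, **estimator_kwargs)
    est.fit(dataset)
    return est.result_()


def fit_cohort(
    datasets: Sequence[ParticipantDataset],
    model_ids: Sequence[str],
    readout: str = "fatigue",
    **estimator_kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, str], FitResult]]:
    """Fit every model to every participant.

    Returns a tidy one-row-per-fit DataFrame and a ``(participant, model)``
    -> FitResult mapping.
    """
    results: dict[tuple[str, str], FitResult] = {}
    rows = []
    for ds in datasets:
        for mid in model_ids:
            fr = fit_participant(mid, ds, readout=readout, **estimator_kwargs)
            results[(ds.participant_id, mid)] = fr
            rows.append(fr.to_row())
        logger.info(
            "participant %s: best model %s",
            ds.participant_id,
            min(
                (results[(ds.participant_id, m)] for m in model_ids),
                key=lambda r: r.aic,
            ).model_id,
        )
    return pd.DataFrame(rows), results
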