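"""Group-level model comparison.

Three complementary summaries over a cohort of per-participant fits:

* summed AIC per model (lower is better);
* best-fit counts — for how many participants each model has the lowest
  AIC (or RSS);
* random-effects Bayesian model selection (RFX-BMS): treating ``-AIC / 2``
  as an approximate log model evidence, a variational Dirichlet scheme
  estimates the population frequency of each model and, by Monte-Carlo
  sampling of the Dirichlet posterior, the exceedance probability that each
  model is the most frequent one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma

__all__ = [
    "EvidenceMatrix",
    "BmsResult",
    "ComparisonResult",
    "invert_aic",
    "rfx_bms",
    "exceedance_probabilities",
    "best_fit_counts",
    "compare_fits",
]

logger = logging.getLogger(__name__)


@dataclass
class EvidenceMatrix:
    """Per-subject, per-model approximate log model evidence."""

    log_evidence: np.ndarray  # (n_subjects, n_models)
    subject_ids: list[str]
    model_ids: list[str]

    def __post_init__(self) -> None:
        self.log_evidence = np.asarray(self.log_evidence, dtype=float)
        if self.log_evidence.ndim != 2:
            raise ValueError("log_evidence must be 2-D (subjects x models)")
        n, k = self.log_evidence.shape
        if len(self.subject_ids) != n or len(self.model_ids) != k:
            raise ValueError("id lists inconsistent with matrix shape")
        if not np.all(np.isfinite(self.log_evidence)):
            raise ValueError("log_evidence must be finite")


def invert_aic(
    aic_matrix,
    subject_ids: Optional[Sequence[str]] = None,
    model_ids: Optional[Sequence[str]] = None,
) -> EvidenceMatrix:
    """Convert per-subject AICs to approximate log evidences (``-AIC / 2``)."""
    aic_arr = np.asarray(aic_matrix, dtype=float)
    if aic_arr.ndim != 2:
        raise ValueError("aic_matrix must be 2-D (subjects x models)")
    n, k = aic_arr.shape
    return EvidenceMatrix(
        log_evidence=-aic_arr / 2.0,
        subject_ids=list(subject_ids) if subject_ids is not None else [str(i) for i in range(n)],
        model_ids=list(model_ids) if model_ids is not None else [str(j) for j in range(k)],
    )


@dataclass
class BmsResult:
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray
    responsibilities: np.ndarray
    n_iter: int


def rfx_bms(
    evidence: EvidenceMatrix | np.ndarray,
    prior_alpha: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BmsResult:
    """Variational random-effects Bayesian model selection.

    Iterates the standard fixed point: each subject's responsibility for
    model k is proportional to ``exp(log_evidence + digamma(alpha_k) -
    digamma(sum alpha))`` (normalised per subject, computed in log space with
    a per-row max subtraction for stability), and the Dirichlet counts are
    ``alpha_k = prior + sum of responsibilities``.  Stops when the largest
    change in alpha falls below ``tol``.

    Returns the posterior Dirichlet parameters and the expected model
    frequencies ``alpha / sum(alpha)``.  With zero subjects the prior is
    returned unchanged.
    """
    if isinstance(evidence, EvidenceMatrix):
        lme = evidence.log_evidence
    else:
        lme = np.asarray(evidence, dtype=float)
    if lme.ndim != 2:
        raise ValueError("evidence must be 2-D (subjects x models)")
    n, k = lme.shape
    if k < 2:
        raise ValueError("need at least 2 models to compare")
    alpha = np.full(k, float(prior_alpha))
    u = np.zeros((n, k))
    if n == 0:
        return BmsResult(alpha, alpha / alpha.sum(), u, 0)
    for it in range(1, max_iter + 1):
        logu = lme + digamma(alpha) - digamma(alpha.sum())
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = prior_alpha + u.sum(axis=0)
        delta = np.abs(alpha_new - alpha).max()
        alpha = alpha_new
        if delta < tol:
            return BmsResult(alpha, alpha / alpha.sum(), u, it)
    raise RuntimeError(
        f"RFX-BMS did not converge in {max_iter} iterations "
        f"(last max |d alpha| = {delta:.3g})"
    )


def exceedance_probabilities(
    dirichlet_alpha, n_samples: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities under a Dirichlet posterior.

    EP_k is the probability that model k's population frequency exceeds every
    other model's.  Estimated from ``n_samples`` Dirichlet draws; seeded and
    reproducible.
    """
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("all Dirichlet parameters must be > 0")
    rng = np.random.default_rng(seed)
    k = alpha.size
    counts = np.zeros(k, dtype=np.int64)
    # draw in chunks to bound memory at ~10 MB
    chunk = 100_000
    remaining = int(n_samples)
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        winners = np.argmax(draws, axis=1)
        counts += np.bincount(winners, minlength=k)
        remaining -= m
    return counts / float(n_samples)


def best_fit_counts(score_matrix, criterion: str = "aic") -> np.ndarray:
    """Per-model count of subjects for whom it has the lowest score.

    Exact ties are awarded to the lowest model index and logged.  The
    ``criterion`` label ("aic" or "rss") is informational only; the scores
    are minimised either way.
    """
    scores = np.asarray(score_matrix, dtype=float)
    if scores.ndim != 2:
        raise ValueError("score_matrix must be 2-D (subjects x models)")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n, k = scores.shape
    counts = np.zeros(k, dtype=int)
    for i in range(n):
        row = scores[i]
        best = int(np.argmin(row))  # argmin takes the first (lowest index) on ties
        if np.sum(row == row[best]) > 1:
            logger.info(
                "subject %d: %s tie between models %s; counted for model %d",
                i, criterion, np.flatnonzero(row == row[best]).tolist(), best,
            )
        counts[best] += 1
    return counts


@dataclass
class ComparisonResult:
    """Group-level comparison over a cohort of fits."""

    model_ids: list[str]
    subject_ids: list[str]
    summed_aic: np.ndarray
    best_count_aic: np.ndarray
    best_count_rss: np.ndarray
    dirichlet_alpha: np.ndarray
    expected_frequency: np.ndarray
    exceedance_probability: np.ndarray
    bms_iterations: int

    @property
    def best_model_id(self) -> str:
        return self.model_ids[int(np.argmax(self.exceedance_probability))]

    def to_dict(self) -> dict:
        per_model = lambda arr: {m: float(v) for m, v in zip(self.model_ids, arr)}
        return {
            "model_ids": self.model_ids,
            "n_subjects": len(self.subject_ids),
            "summed_aic": per_model(self.summed_aic),
            "best_count_aic": {m: int(v) for m, v in zip(self.model_ids, self.best_count_aic)},
            "best_count_rss": {m: int(v) for m, v in zip(self.model_ids, self.best_count_rss)},
            "dirichlet_alpha": per_model(self.dirichlet_alpha),
            "expected_frequency": per_model(self.expected_frequency),
            "exceedance_probability": per_model(self.exceedance_probability),
            "best_model": self.best_model_id,
            "bms_iterations": self.bms_iterations,
        }


def compare_fits(
    fits: pd.DataFrame,
    prior_alpha: float = 1.0,
    tol: float = 1e-6,
    ep_samples: int = 1_000_000,
    seed: int = 0,
) -> ComparisonResult:
    """Full group-level comparison from a tidy fits table.

    ``fits`` needs columns ``participant, model_id, aic, rss`` (one row per
    participant x model, complete cases only).
    """
    for col in ("participant", "model_id", "aic", "rss"):
        if col not in fits.columns:
            raise ValueError(f"fits table is missing required column {col!r}")
    aic_wide = fits.pivot(index="participant", columns="model_id", values="aic")
    rss_wide = fits.pivot(index="participant", columns="model_id", values="rss")
    if aic_wide.isna().any().any():
        missing = aic_wide.isna().stack()
        raise ValueError(
            f"incomplete fits: missing {missing[missing].index.tolist()[:5]} ..."
        )
    model_ids = list(aic_wide.columns)
    subject_ids = [str(s) for s in aic_wide.index]
    aic_mat = aic_wide.to_numpy()
    rss_mat = rss_wide[model_ids].to_numpy()

    evidence = invert_aic(aic_mat, subject_ids, model_ids)
    bms = rfx_bms(evidence, prior_alpha=prior_alpha, tol=tol)
    ep = exceedance_probabilities(bms.dirichlet_alpha, n_samples=ep_samples, seed=seed)
    return ComparisonResult(
        model_ids=model_ids,
        subject_ids=subject_ids,
        summed_aic=aic_mat.sum(axis=0),
        best_count_aic=best_fit_counts(aic_mat, "aic"),
        best_count_rss=best_fit_counts(rss_mat, "rss"),
        dirichlet_alpha=bms.dirichlet_alpha,
        expected_frequency=bms.expected_frequency,
        exceedance_probability=ep,
        bms_iterations=bms.n_iter,
    )
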