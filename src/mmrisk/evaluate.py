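"""Challenge scoring: sliding-threshold iAUC, weighted metrics, bootstrap
Bayes-factor tie detection and leaderboard ranking.

High risk is defined as disease progression or death before a time threshold
(18 months by default).  At a given threshold a patient is

* labeled 1 if they progressed/died before the threshold,
* labeled 0 if they were followed (event or censored) past it,
* not evaluable if censored before the threshold — such patients carry no
  information about the binary outcome and are excluded at that threshold.

The primary metric slides the threshold weekly from 12 to 24 months and
averages the Mann-Whitney AUC over the grid (iAUC).  Per-cohort iAUCs are
combined with weights equal to the squared count of high-risk patients at the
18-month center (wiAUC); the same weighting applied to balanced accuracy gives
wBAC, the tie-breaking metric.  Ties are declared by the Bayes factor K — the
paired-bootstrap win ratio against the top model — with K < 3 counted as a
statistical tie.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    MissingPredictionError,
    NegativeTimeError,
    UndefinedMetricError,
)
from .simulate import Cohort

__all__ = [
    "ThresholdGrid",
    "RiskPrediction",
    "CohortEvaluation",
    "EvaluationResult",
    "label_high_risk",
    "auc_at_threshold",
    "iauc",
    "iauc_curve",
    "weighted_metric",
    "bac",
    "evaluate_cohort",
    "evaluate_model",
    "bootstrap_wiauc",
    "bayes_factor",
    "rank_models",
    "km_estimate",
]

logger = logging.getLogger(__name__)

#: one week expressed in (mean Gregorian) months
WEEK_MONTHS = 7.0 / 30.4375

TIE_BAYES_FACTOR = 3.0  # K < 3 counts as a statistical tie (strict)


@dataclass(frozen=True)
class ThresholdGrid:
    """Sliding PFS-threshold grid: weekly steps from 12 to 24 months,
    centered on 18."""

    center_months: float = 18.0
    start_months: float = 12.0
    end_months: float = 24.0
    step_months: float = WEEK_MONTHS

    def __post_init__(self) -> None:
        if not self.start_months < self.center_months < self.end_months:
            raise ValueError("need start < center < end")
        if self.step_months <= 0:
            raise ValueError("step must be positive")
        asym = abs((self.center_months - self.start_months)
                   - (self.end_months - self.center_months))
        if asym > self.step_months:
            raise ValueError("grid must be symmetric about the center "
                             "within one step")

    def thresholds(self) -> np.ndarray:
        k = int(math.floor((self.end_months - self.start_months)
                           / self.step_months + 1e-9))
        return self.start_months + self.step_months * np.arange(k + 1)


@dataclass
class RiskPrediction:
    """One model's predictions on one cohort: continuous risk scores (higher =
    higher risk) and optional binary high-risk calls, both patient-indexed."""

    model_id: str
    cohort_id: str
    scores: pd.Series
    binary_calls: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(float)).all():
            raise ValueError(
                f"non-finite score in predictions of {self.model_id} "
                f"on {self.cohort_id}"
            )


@dataclass
class CohortEvaluation:
    cohort_id: str
    n_high_risk: int
    iauc: float
    bac: float | None
    per_threshold_aucs: list[float | None]
    n_undefined_thresholds: int = 0

    @property
    def weight(self) -> int:
        return self.n_high_risk ** 2


@dataclass
class EvaluationResult:
    model_id: str
    cohort_evaluations: list[CohortEvaluation]
    wiauc: float
    wbac: float | None
    bootstrap_wiaucs: np.ndarray = field(default_factory=lambda: np.array([]))
    bayes_factor_vs_top: float = float("nan")
    tied_with_top: bool = False
    final_rank: int = 0


# ---------------------------------------------------------------------------
# labels and per-threshold AUC


def _as_arrays(survival: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    times = survival["pfs_months"].to_numpy(float)
    events = survival["pfs_event"].to_numpy(int)
    if (times < 0).any():
        raise NegativeTimeError("negative PFS time")
    return times, events


def label_high_risk(
    survival: pd.DataFrame, threshold_months: float = 18.0
) -> tuple[pd.Series, pd.Series]:
    """High-risk labels at a threshold, plus the evaluability mask.

    Label 1: progressed/died before the threshold.  Label 0: followed past it.
    Censored before the threshold: not evaluable.
    """
    times, events = _as_arrays(survival)
    labels, evaluable = _label_arrays(times, events, threshold_months)
    idx = survival.index
    return pd.Series(labels, index=idx), pd.Series(evaluable, index=idx)


def _label_arrays(times, events, threshold):
    high = (times < threshold) & (events == 1)
    evaluable = ~((times < threshold) & (events == 0))
    return high.astype(int), evaluable


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Midrank AUC of scores for label 1 vs 0; None when a class is empty."""
    n1 = int(labels.sum())
    n0 = labels.shape[0] - n1
    if n1 == 0 or n0 == 0:
        return None
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _aligned_scores(prediction: RiskPrediction, survival: pd.DataFrame,
                    evaluable: np.ndarray | None = None) -> np.ndarray:
    missing = survival.index.difference(prediction.scores.index)
    if evaluable is not None:
        missing = [p for p in missing
                   if evaluable[survival.index.get_loc(p)]]
    if len(missing):
        raise MissingPredictionError(
            f"model {prediction.model_id}: no prediction for evaluable "
            f"patient(s) {sorted(map(str, missing))[:5]} in cohort "
            f"{prediction.cohort_id}"
        )
    return prediction.scores.reindex(survival.index).to_numpy(float)


def auc_at_threshold(
    prediction: RiskPrediction, survival: pd.DataFrame, threshold_months: float
) -> float | None:
    """Mann-Whitney AUC among evaluable patients at one threshold; ties count
    1/2; None (flagged, not 0) when either outcome class is empty."""
    times, events = _as_arrays(survival)
    labels, evaluable = _label_arrays(times, events, threshold_months)
    scores = _aligned_scores(prediction, survival, evaluable)
    auc = _mann_whitney_auc(scores[evaluable], labels[evaluable])
    if auc is None:
        logger.debug("AUC undefined at threshold %.3f for %s/%s",
                     threshold_months, prediction.model_id, prediction.cohort_id)
    return auc


def _iauc_arrays(
    scores: np.ndarray, times: np.ndarray, events: np.ndarray,
    thresholds: np.ndarray,
) -> tuple[float | None, list[float | None]]:
    aucs: list[float | None] = []
    for thr in thresholds:
        labels, evaluable = _label_arrays(times, events, thr)
        aucs.append(_mann_whitney_auc(scores[evaluable], labels[evaluable]))
    defined = [a for a in aucs if a is not None]
    return (float(np.mean(defined)) if defined else None), aucs


def iauc_curve(
    prediction: RiskPrediction, survival: pd.DataFrame,
    grid: ThresholdGrid | None = None,
) -> tuple[np.ndarray, list[float | None]]:
    """Per-threshold AUCs over the grid (None where undefined)."""
    grid = grid or ThresholdGrid()
    times, events = _as_arrays(survival)
    scores = _aligned_scores(prediction, survival)
    thresholds = grid.thresholds()
    _, aucs = _iauc_arrays(scores, times, events, thresholds)
    return thresholds, aucs


def iauc(
    prediction: RiskPrediction, survival: pd.DataFrame,
    grid: ThresholdGrid | None = None,
) -> float:
    """Mean of the defined per-threshold AUCs over the sliding grid.

    Invariant under strictly monotone transforms of the scores; undefined
    thresholds are skipped (and counted by :func:`iauc_curve`).
    """
    grid = grid or ThresholdGrid()
    _, aucs = iauc_curve(prediction, survival, grid)
    defined = [a for a in aucs if a is not None]
    if not defined:
        raise UndefinedMetricError(
            f"AUC undefined at every grid threshold for {prediction.model_id} "
            f"on {prediction.cohort_id}"
        )
    return float(np.mean(defined))


# ---------------------------------------------------------------------------
# weighting, BAC


def weighted_metric(per_cohort: list[tuple[float, int]]) -> float:
    """Squared-high-risk-count weighting: sum(n^2 m) / sum(n^2)."""
    weights = np.array([n ** 2 for _, n in per_cohort], float)
    if weights.sum() == 0:
        raise UndefinedMetricError("all cohort weights are zero")
    values = np.array([m for m, _ in per_cohort], float)
    keep = weights > 0
    return float(np.sum(weights[keep] * values[keep]) / weights[keep].sum())


def bac(
    binary_calls: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    evaluable: pd.Series | np.ndarray,
) -> float | None:
    """Balanced accuracy (sensitivity + specificity)/2 on evaluable patients;
    None (flagged) when an outcome class is absent."""
    calls = np.asarray(binary_calls, int)[np.asarray(evaluable, bool)]
    labs = np.asarray(labels, int)[np.asarray(evaluable, bool)]
    pos, neg = labs == 1, labs == 0
    if pos.sum() == 0 or neg.sum() == 0:
        logger.debug("BAC undefined: an outcome class is empty")
        return None
    sens = float((calls[pos] == 1).mean())
    spec = float((calls[neg] == 0).mean())
    return (sens + spec) / 2.0


# ---------------------------------------------------------------------------
# cohort / model evaluation


def evaluate_cohort(
    prediction: RiskPrediction, cohort: Cohort,
    grid: ThresholdGrid | None = None,
) -> CohortEvaluation:
    """iAUC, BAC and high-risk weight of one model on one cohort.

    Binary calls default to dichotomizing the scores at the observed high-risk
    prevalence at the grid center.
    """
    from .signatures import dichotomize_scores

    grid = grid or ThresholdGrid()
    survival = cohort.survival
    labels, evaluable = label_high_risk(survival, grid.center_months)
    n_high = int(labels[evaluable].sum())

    thresholds, aucs = iauc_curve(prediction, survival, grid)
    defined = [a for a in aucs if a is not None]
    if not defined:
        raise UndefinedMetricError(
            f"iAUC undefined on cohort {cohort.cohort_id}"
        )
    calls = prediction.binary_calls
    if calls is None:
        calls = dichotomize_scores(prediction.scores, survival, grid.center_months)
    calls = calls.reindex(survival.index).fillna(0).astype(int)
    return CohortEvaluation(
        cohort_id=cohort.cohort_id,
        n_high_risk=n_high,
        iauc=float(np.mean(defined)),
        bac=bac(calls, labels, evaluable),
        per_threshold_aucs=aucs,
        n_undefined_thresholds=len(aucs) - len(defined),
    )


def evaluate_model(
    model_id: str,
    predictions: list[RiskPrediction],
    cohorts: list[Cohort],
    grid: ThresholdGrid | None = None,
) -> EvaluationResult:
    """Point wiAUC / wBAC of one model across cohorts."""
    grid = grid or ThresholdGrid()
    by_cohort = {c.cohort_id: c for c in cohorts}
    evals = [
        evaluate_cohort(p, by_cohort[p.cohort_id], grid)
        for p in predictions
        if p.model_id == model_id
    ]
    if not evals:
        raise ValueError(f"no predictions for model {model_id!r}")
    wiauc = weighted_metric([(e.iauc, e.n_high_risk) for e in evals])
    bac_pairs = [(e.bac, e.n_high_risk) for e in evals if e.bac is not None]
    wbac = weighted_metric(bac_pairs) if bac_pairs else None
    return EvaluationResult(model_id, evals, wiauc, wbac)


# ---------------------------------------------------------------------------
# paired bootstrap and Bayes factor


def bootstrap_wiauc(
    predictions: list[RiskPrediction],
    cohorts: list[Cohort],
    grid: ThresholdGrid | None = None,
    B: int = 1000,
    seed: int = 0,
    resample: bool = True,
    max_retries: int = 100,
) -> dict[str, np.ndarray]:
    """B paired-bootstrap wiAUC draws per model.

    Patients are resampled with replacement within each cohort using one
    shared index draw across models (paired bootstrap), so per-draw
    differences between models reflect the models, not resampling noise.
    A replicate with zero high-risk weight in every cohort is redrawn, up to
    ``max_retries`` times.  ``resample=False`` is a test hook that uses
    identity indices.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    grid = grid or ThresholdGrid()
    thresholds = grid.thresholds()
    by_cohort = {c.cohort_id: c for c in cohorts}
    model_ids = sorted({p.model_id for p in predictions})
    cohort_ids = sorted({p.cohort_id for p in predictions})

    # align everything to numpy once
    arrays: dict[tuple[str, str], np.ndarray] = {}
    surv: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cid in cohort_ids:
        surv[cid] = _as_arrays(by_cohort[cid].survival)
    for p in predictions:
        arrays[(p.model_id, p.cohort_id)] = _aligned_scores(
            p, by_cohort[p.cohort_id].survival
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = {m: np.empty(B) for m in model_ids}
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = {}
            for cid in cohort_ids:
                n = surv[cid][0].shape[0]
                idx[cid] = rng.integers(0, n, n) if resample else np.arange(n)
            # weights are model-independent under the shared index draw
            weights = {}
            for cid in cohort_ids:
                t, e = surv[cid]
                t_b, e_b = t[idx[cid]], e[idx[cid]]
                labels, evaluable = _label_arrays(t_b, e_b, grid.center_months)
                weights[cid] = int(labels[evaluable].sum()) ** 2
            if sum(weights.values()) > 0:
                break
        else:
            raise UndefinedMetricError(
                f"bootstrap replicate {b}: no high-risk patients in any "
                f"cohort after {max_retries} redraws"
            )
        for m in model_ids:
            num = den = 0.0
            for cid in cohort_ids:
                if weights[cid] == 0 or (m, cid) not in arrays:
                    continue
                t, e = surv[cid]
                s_b = arrays[(m, cid)][idx[cid]]
                ia, _ = _iauc_arrays(s_b, t[idx[cid]], e[idx[cid]], thresholds)
                if ia is None:
                    continue
                num += weights[cid] * ia
                den += weights[cid]
            draws[m][b] = num / den if den > 0 else np.nan
    return draws


def bayes_factor(top_draws: np.ndarray, other_draws: np.ndarray) -> float:
    """Paired-bootstrap win ratio K of the top model over a contender.

    Exact per-draw ties split evenly between numerator and denominator, so
    K(x, x) = 1.  All-wins returns infinity.
    """
    top = np.asarray(top_draws, float)
    other = np.asarray(other_draws, float)
    if top.shape != other.shape:
        raise ValueError("paired draw lists must have equal length")
    wins = float(np.sum(top > other))
    losses = float(np.sum(top < other))
    ties = float(np.sum(top == other))
    num = wins + ties / 2.0
    den = losses + ties / 2.0
    if den == 0:
        return math.inf
    return num / den


def rank_models(evaluations: list[EvaluationResult]) -> list[EvaluationResult]:
    """Final leaderboard ordering.

    Sort by wiAUC descending; compute K for every model against the top;
    among the statistically tied set (K < 3, including the top itself) the
    model with the highest wBAC takes rank 1; the remainder follow in wiAUC
    order.  Residual ties break by model_id, so the ordering is deterministic.
    """
    if not evaluations:
        raise ValueError("no models to rank")
    ordered = sorted(evaluations, key=lambda e: (-e.wiauc, e.model_id))
    top = ordered[0]
    for e in ordered:
        if len(top.bootstrap_wiaucs) and len(e.bootstrap_wiaucs):
            e.bayes_factor_vs_top = bayes_factor(
                top.bootstrap_wiaucs, e.bootstrap_wiaucs
            )
        else:
            e.bayes_factor_vs_top = 1.0 if e is top else math.inf
        e.tied_with_top = e.bayes_factor_vs_top < TIE_BAYES_FACTOR
    tied = [e for e in ordered if e.tied_with_top]
    winner = max(
        tied, key=lambda e: (e.wbac if e.wbac is not None else -math.inf,
                             e.model_id)
    )
    final = [winner] + [e for e in ordered if e is not winner]
    for rank, e in enumerate(final, start=1):
        e.final_rank = rank
    return final


def leaderboard_frame(evaluations: list[EvaluationResult]) -> pd.DataFrame:
    """Leaderboard as a tidy table (one row per model, rank order)."""
    rows = [
        {
            "final_rank": e.final_rank,
            "model_id": e.model_id,
            "wiauc": e.wiauc,
            "wbac": e.wbac,
            "bayes_factor_vs_top": e.bayes_factor_vs_top,
            "tied_with_top": e.tied_with_top,
        }
        for e in sorted(evaluations, key=lambda e: e.final_rank)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier (reporting aid)


def km_estimate(
    survival: pd.DataFrame,
    time_col: str = "pfs_months",
    event_col: str = "pfs_event",
):
    """Product-limit survival estimate; thin wrapper around lifelines."""
    from lifelines import KaplanMeierFitter

    times = survival[time_col].to_numpy(float)
    if (times < 0).any():
        raise NegativeTimeError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, survival[event_col].to_numpy(int))
    return kmf
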