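"""Repeated participant-stratified cross-validation and the rolling
data-availability harness.

Both model arms are evaluated on the identical pool of (participant, day,
task) predictions at each availability level D in {15, 30, 45, 60, 75}:

* SSM arm — per test participant and day t >= D, a MAP model is fit on EMA
  days (t-D+1..t] and lapse days (t-D+1..t-1] (the Figure-style rolling
  window: with D=15 the day-18 prediction trains on EMA days 4-18 and lapse
  days 4-17), using priors built from training-fold participants; risk scores
  come from playing the fitted model forward.
* Classifier arm — one population model per task, tuned and trained on
  full-history features of training-fold participants, then applied to
  availability-D test featurizations.

Fold-level AUROC / AUPRC values feed the posterior comparison module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import Cohort
from .features import (
    TuningGrid,
    build_feature_table,
    predict_scores,
    tune_and_fit,
)
from .ssm import (
    PriorSpec,
    SsmParams,
    build_priors,
    fit_map_obs,
    kalman_filter,
    predict_risk,
    series_to_obs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CvScheme",
    "stratified_group_folds",
    "run_ssm_arm",
    "run_classifier_arm",
    "run_benchmark",
    "compute_auroc",
    "compute_auprc",
    "performance_table",
]

DEFAULT_AVAILABILITIES = (15, 30, 45, 60, 75)
DEFAULT_TASKS = (0, 3, 7)


@dataclass
class CvScheme:
    n_repeats: int = 15
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def stratified_group_folds(
    cohort: Cohort, scheme: CvScheme
) -> list[dict[str, int]]:
    """Participant-level fold assignment per repeat, balancing positive rates.

    Greedy: participants are shuffled (seeded per repeat), ordered by lapse
    count descending, and each is assigned to the fold with the fewest
    positives so far (ties to the fewest days, then lowest index), which keeps
    positive proportions and fold sizes jointly balanced. All of a
    participant's days land in exactly one fold.
    """
    if len(cohort) < scheme.n_folds:
        raise ValueError("fewer participants than folds")
    pos = {p.participant_id: int(p.lapse.sum()) for p in cohort}
    days = {p.participant_id: p.study_length for p in cohort}
    ids = sorted(pos)
    out = []
    for rep in range(scheme.n_repeats):
        rng = np.random.default_rng([scheme.seed, rep])
        order = list(rng.permutation(ids))
        order.sort(key=lambda pid: -pos[pid])  # stable: keeps shuffled ties
        fold_pos = np.zeros(scheme.n_folds)
        fold_days = np.zeros(scheme.n_folds)
        assign: dict[str, int] = {}
        for pid in order:
            # fewest positives so far, then fewest days: keeps positive
            # proportions and fold sizes jointly balanced
            best_f = min(
                range(scheme.n_folds),
                key=lambda f: (fold_pos[f], fold_days[f], f),
            )
            assign[pid] = best_f
            fold_pos[best_f] += pos[pid]
            fold_days[best_f] += days[pid]
        out.append(assign)
    return out


# ---------------------------------------------------------------------------
# SSM arm
# ---------------------------------------------------------------------------


def run_ssm_arm(
    cohort: Cohort,
    test_ids: list[str],
    priors: PriorSpec,
    availability: int,
    tasks: tuple[int, ...] = DEFAULT_TASKS,
    seed: int = 0,
    maxiter_cold: int = 150,
    maxiter_warm: int = 40,
) -> pd.DataFrame:
    """Rolling MAP fits + forward-simulation scores for the test participants.

    Day t's fit is warm-started at day t-1's solution (the windows overlap in
    all but two days), which keeps the per-day refitting protocol desk-scale.
    Returns one record per (participant, day, task) with eligible windows.
    """
    if availability < 2:
        raise ValueError("availability must be >= 2")
    records = []
    n_failed = 0
    for pid in test_ids:
        series = cohort.get(pid)
        T = series.study_length
        prev: SsmParams | None = None
        for t in range(availability, T + 1):
            if t + min(tasks) > T:
                break
            ema_win = (t - availability + 1, t)
            lapse_win = (t - availability + 1, t - 1)
            y, mask = series_to_obs(series, ema_win, lapse_win, cohort.ordinal_scale)
            try:
                fit = fit_map_obs(
                    y, mask, priors,
                    init=prev, seed=seed, n_restarts=1,
                    maxiter=maxiter_warm if prev is not None else maxiter_cold,
                )
                prev = fit.params
                fr = kalman_filter(fit.params, (y, mask))
            except (FloatingPointError, np.linalg.LinAlgError) as exc:
                n_failed += 1
                logger.warning("SSM fit failed for %s day %d: %s", pid, t, exc)
                prev = None
                continue
            m, P = fr.filt_mean[-1], fr.filt_cov[-1]
            for k in tasks:
                if t + k > T:
                    continue
                score = predict_risk(fit.params, m, P, k, method="analytic")
                records.append(
                    {
                        "model_id": "ssm",
                        "task": k,
                        "availability": availability,
                        "participant_id": pid,
                        "day": t,
                        "score": score,
                        "label": int(series.lapse[t - 1 : t - 1 + k + 1].max()),
                    }
                )
    if n_failed:
        warnings.warn(f"{n_failed} SSM fit(s) failed and were skipped")
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Classifier arm
# ---------------------------------------------------------------------------


def run_classifier_arm(
    cohort: Cohort,
    test_ids: list[str],
    train_ids: list[str],
    family: str,
    availabilities: tuple[int, ...],
    tasks: tuple[int, ...] = DEFAULT_TASKS,
    grid: TuningGrid | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Tune/train per task on full-history training-fold features, then score
    availability-restricted test featurizations (test-time-only restriction)."""
    drop_one = family == "lr"
    fills = _population_item_means(cohort, train_ids)
    records = []
    for k in tasks:
        train_rows = build_feature_table(
            cohort, task=k, availability=None, participant_ids=train_ids,
            drop_one=drop_one, fill_values=fills,
        )
        fitted = tune_and_fit(train_rows, family, grid=grid, seed=seed)
        for D in availabilities:
            test_rows = build_feature_table(
                cohort, task=k, availability=D, participant_ids=test_ids,
                drop_one=drop_one, fill_values=fills,
            )
            if test_rows.empty:
                continue
            scores = predict_scores(fitted, test_rows)
            for (_, row), s in zip(test_rows.iterrows(), scores):
                records.append(
                    {
                        "model_id": family,
                        "task": k,
                        "availability": D,
                        "participant_id": row["participant_id"],
                        "day": int(row["day"]),
                        "score": float(s),
                        "label": int(row["label"]),
                    }
                )
    return pd.DataFrame(records)


def _population_item_means(cohort: Cohort, train_ids: list[str]) -> np.ndarray:
    mats = [cohort.scale01(cohort.get(pid).ema_matrix()) for pid in train_ids]
    stacked = np.vstack(mats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(stacked, axis=0)
    return np.where(np.isnan(means), 0.5, means)


# ---------------------------------------------------------------------------
# Full benchmark driver
# ---------------------------------------------------------------------------


def run_benchmark(
    cohort: Cohort,
    scheme: CvScheme | None = None,
    models: tuple[str, ...] = ("ssm", "lr", "xgb"),
    availabilities: tuple[int, ...] = DEFAULT_AVAILABILITIES,
    tasks: tuple[int, ...] = DEFAULT_TASKS,
    seed: int = 0,
    grids: dict[str, TuningGrid] | None = None,
    sd_floor: float = 0.05,
) -> pd.DataFrame:
    """Run every (repeat, fold, model, availability, task) cell.

    SSM priors are rebuilt per (repeat, fold) from the training folds'
    full-trajectory MLE estimates; those per-participant estimates are cached
    across folds (they depend only on the participant's own data). Returns the
    pooled PredictionRecord table.
    """
    scheme = scheme or CvScheme()
    folds = stratified_group_folds(cohort, scheme)
    mle_cache: dict[str, SsmParams] = {}
    all_records = []
    for rep, assign in enumerate(folds):
        for fold in range(scheme.n_folds):
            test_ids = sorted(pid for pid, f in assign.items() if f == fold)
            train_ids = sorted(pid for pid, f in assign.items() if f != fold)
            if not test_ids:
                continue
            cell_records = []
            if "ssm" in models:
                priors = build_priors(
                    cohort.subset(train_ids), sd_floor=sd_floor, seed=seed,
                    mle_cache=mle_cache,
                )
                for D in availabilities:
                    rec = run_ssm_arm(
                        cohort, test_ids, priors, D, tasks, seed=seed
                    )
                    cell_records.append(rec)
            for family in models:
                if family == "ssm":
                    continue
                rec = run_classifier_arm(
                    cohort, test_ids, train_ids, family, availabilities,
                    tasks, grid=(grids or {}).get(family), seed=seed,
                )
                cell_records.append(rec)
            for rec in cell_records:
                if not rec.empty:
                    rec = rec.assign(repeat=rep, fold=fold)
                    all_records.append(rec)
    return pd.concat(all_records, ignore_index=True)


# ---------------------------------------------------------------------------
# Fold-level metrics
# ---------------------------------------------------------------------------


def compute_auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUROC with ties counted half; raises on single-class pools."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined for a single-class pool")
    return float(roc_auc_score(labels, scores))


def compute_auprc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Step-interpolated precision-recall area (average precision)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPRC undefined for a single-class pool")
    return float(average_precision_score(labels, scores))


def performance_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(model, task, availability, repeat, fold) AUROC/AUPRC.

    Single-class pools yield NaN metrics (flagged, counted in a warning) and
    are excluded from downstream posterior modelling.
    """
    rows = []
    n_missing = 0
    keys = ["model_id", "task", "availability", "repeat", "fold"]
    for key_vals, grp in records.groupby(keys, sort=True):
        row = dict(zip(keys, key_vals))
        row["n"] = len(grp)
        row["n_pos"] = int(grp["label"].sum())
        try:
            row["auroc"] = compute_auroc(grp["label"], grp["score"])
            row["auprc"] = compute_auprc(grp["label"], grp["score"])
        except ValueError:
            row["auroc"] = np.nan
            row["auprc"] = np.nan
            n_missing += 1
        rows.append(row)
    if n_missing:
        warnings.warn(f"{n_missing} single-class fold cell(s) recorded as missing")
    return pd.DataFrame(rows)
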