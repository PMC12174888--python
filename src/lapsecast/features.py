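"""Population-level benchmark classifiers on hand-built EMA features.

Logistic regression and gradient-boosted trees are trained at the cohort
level on a fixed feature set per participant-day: day-of-week one-hot (one
column dropped for the linear model to avoid collinearity), the most recent
available morning-EMA responses scaled to [0, 1], short-run (last 3 available
EMAs) and long-run (all available EMAs in the availability window) means, and
three booleans flagging any lapse in the last 1, 3 and 5 days. At training
time features use the full history up to each day; availability-restricted
featurization applies only at test time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold
from xgboost import XGBClassifier

from .cohort import Cohort, N_ITEMS, ParticipantSeries

__all__ = [
    "FeatureRow",
    "TuningGrid",
    "FittedModel",
    "feature_columns",
    "featurize",
    "build_feature_table",
    "tune_and_fit",
    "predict_scores",
    "default_grid",
]

_DOW_COLS = [f"dow_{d}" for d in range(7)]
_LATEST_COLS = [f"latest_{i}" for i in range(1, N_ITEMS + 1)]
_SHORT_COLS = [f"short_{i}" for i in range(1, N_ITEMS + 1)]
_LONG_COLS = [f"long_{i}" for i in range(1, N_ITEMS + 1)]
_LAPSE_COLS = ["lapse_last1", "lapse_last3", "lapse_last5"]
IMPUTED_FLAG = "ema_imputed"  # extra indicator, not part of the core 37


def feature_columns(drop_one: bool = False) -> list[str]:
    """The core feature schema: 7+9+9+9+3 = 37 columns (36 in drop-one mode,
    which removes the final weekday column for the linear model)."""
    dow = _DOW_COLS[:-1] if drop_one else _DOW_COLS
    return dow + _LATEST_COLS + _SHORT_COLS + _LONG_COLS + _LAPSE_COLS


@dataclass
class FeatureRow:
    participant_id: str
    day: int
    availability: int
    values: dict[str, float]
    label: int | None = None


@dataclass
class TuningGrid:
    """Named hyperparameter lists, inner-CV fold count, selection metric."""

    grid: dict[str, list]
    n_inner_folds: int = 5
    metric: str = "auroc"

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must be non-empty")

    def settings(self):
        keys = sorted(self.grid)
        for combo in itertools.product(*(self.grid[k] for k in keys)):
            yield dict(zip(keys, combo))


def default_grid(family: str) -> TuningGrid:
    if family == "lr":
        return TuningGrid(
            {"C": [0.01, 0.1, 1.0, 10.0], "class_weight": [None, "balanced"]}
        )
    if family == "xgb":
        return TuningGrid(
            {
                "max_depth": [2, 3, 4],
                "learning_rate": [0.05, 0.1],
                "n_estimators": [100, 300],
                "subsample": [0.7, 1.0],
            }
        )
    raise ValueError(f"unknown model family {family!r}")


def featurize(
    series: ParticipantSeries,
    day: int,
    availability: int,
    ordinal_scale: tuple[int, int] = (1, 5),
    drop_one: bool = False,
    fill_values: np.ndarray | None = None,
) -> FeatureRow:
    """Build one participant-day feature row using only days <= ``day``.

    EMA-derived features draw on observed morning EMAs within the availability
    window ``(day - availability, day]``. If that window contains none, the
    most recent pre-window EMA is carried forward; failing that, ``fill_values``
    (e.g. training-population item means on the [0,1] scale, default mid-scale)
    are imputed — either way the ``ema_imputed`` flag is set. Lapse booleans
    cover days day-1, day-1..day-3 and day-1..day-5, clipped at day 1.
    """
    if day < availability:
        raise ValueError("day must be >= availability")
    if day > series.study_length:
        raise ValueError("day beyond study period")
    smin, smax = ordinal_scale
    raw = series.ema_matrix()[:day]  # never touches days > day
    scaled = (raw - smin) / (smax - smin)
    win_lo = day - availability  # 0-based exclusive lower bound
    observed_days = np.where(~np.isnan(raw).all(axis=1))[0]
    in_win = observed_days[observed_days >= win_lo]
    vals: dict[str, float] = {}
    wd = (series.start_weekday + day - 1) % 7
    for d, col in enumerate(_DOW_COLS):
        vals[col] = 1.0 if d == wd else 0.0
    imputed = False
    if in_win.size:
        latest = scaled[in_win[-1]]
        short = np.nanmean(scaled[in_win[-3:]], axis=0)
        long = np.nanmean(scaled[in_win], axis=0)
    else:
        imputed = True
        pre = observed_days  # all observed are pre-window here
        if pre.size:
            latest = scaled[pre[-1]]
        elif fill_values is not None:
            latest = np.asarray(fill_values, dtype=float)
        else:
            latest = np.full(N_ITEMS, 0.5)
        short = long = latest
    # item-level gaps inside an observed EMA: fall back to mid-scale
    latest = np.where(np.isnan(latest), 0.5, latest)
    short = np.where(np.isnan(short), 0.5, short)
    long = np.where(np.isnan(long), 0.5, long)
    for i in range(N_ITEMS):
        vals[_LATEST_COLS[i]] = float(latest[i])
        vals[_SHORT_COLS[i]] = float(short[i])
        vals[_LONG_COLS[i]] = float(long[i])
    lapse = series.lapse
    for col, back in zip(_LAPSE_COLS, (1, 3, 5)):
        lo = max(day - 1 - back, 0)
        vals[col] = float(lapse[lo : day - 1].max()) if day > 1 else 0.0
    vals[IMPUTED_FLAG] = float(imputed)
    if drop_one:
        vals.pop(_DOW_COLS[-1])
    return FeatureRow(series.participant_id, day, availability, vals)


def build_feature_table(
    cohort: Cohort,
    task: int,
    availability: int | None = None,
    participant_ids: list[str] | None = None,
    drop_one: bool = False,
    fill_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Feature rows for every eligible (participant, day) with task labels.

    ``availability=None`` means full-history featurization (training mode:
    every day from 1 while the k-day window fits). With an integer
    availability (test mode) rows start at that day.
    """
    rows = []
    for p in cohort:
        if participant_ids is not None and p.participant_id not in participant_ids:
            continue
        first = 1 if availability is None else availability
        for t in range(first, p.study_length - task + 1):
            D = t if availability is None else availability
            fr = featurize(p, t, D, cohort.ordinal_scale, drop_one, fill_values)
            row = {"participant_id": p.participant_id, "day": t,
                   "label": int(p.lapse[t - 1 : t - 1 + task + 1].max())}
            row.update(fr.values)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FittedModel:
    family: str
    model: object
    columns: list[str]
    best_setting: dict
    inner_scores: dict


def _make_estimator(family: str, setting: dict, seed: int):
    if family == "lr":
        return LogisticRegression(
            C=setting.get("C", 1.0),
            class_weight=setting.get("class_weight"),
            max_iter=2000,
            solver="lbfgs",
            random_state=seed,
        )
    if family == "xgb":
        return XGBClassifier(
            max_depth=setting.get("max_depth", 3),
            learning_rate=setting.get("learning_rate", 0.1),
            n_estimators=setting.get("n_estimators", 100),
            subsample=setting.get("subsample", 1.0),
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(f"unknown model family {family!r}")


def tune_and_fit(
    train_rows: pd.DataFrame,
    family: str,
    grid: TuningGrid | None = None,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> FittedModel:
    """Grid search by inner participant-stratified CV (AUROC), then refit.

    Folds are formed with scikit-learn's StratifiedGroupKFold so all of a
    participant's rows share a fold and positive proportions stay balanced.
    Inner folds whose validation pool is single-class are skipped.
    """
    if grid is None:
        grid = default_grid(family)
    if feature_cols is None:
        feature_cols = feature_columns(drop_one=(family == "lr")) + [IMPUTED_FLAG]
    groups = train_rows["participant_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need rows from at least 2 participants")
    X = train_rows[feature_cols].to_numpy(dtype=float)
    y = train_rows["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    n_splits = min(grid.n_inner_folds, len(np.unique(groups)))
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y, groups))
    scores: dict = {}
    best_setting, best_score = None, -np.inf
    for setting in grid.settings():  # deterministic order; first best wins ties
        fold_scores = []
        for tr, va in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
                continue
            est = _make_estimator(family, setting, seed)
            est.fit(X[tr], y[tr])
            fold_scores.append(roc_auc_score(y[va], est.predict_proba(X[va])[:, 1]))
        score = float(np.mean(fold_scores)) if fold_scores else -np.inf
        scores[tuple(sorted(setting.items()))] = score
        if score > best_score:
            best_setting, best_score = setting, score
    if best_setting is None:
        raise RuntimeError("no tunable setting could be scored")
    final = _make_estimator(family, best_setting, seed)
    final.fit(X, y)
    return FittedModel(family=family, model=final, columns=list(feature_cols),
                       best_setting=best_setting, inner_scores=scores)


def predict_scores(fitted: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    """Probability scores in [0, 1], one per row, in row order."""
    missing = [c for c in fitted.columns if c not in rows.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns {missing}")
    X = rows[fitted.columns].to_numpy(dtype=float)
    return fitted.model.predict_proba(X)[:, 1]
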