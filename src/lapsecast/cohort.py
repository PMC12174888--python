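"""Data model, label construction and CSV I/O for daily-EMA lapse cohorts.

A cohort is a set of participants followed for ``T`` days. Each morning a
participant may complete a 9-item ordinal EMA survey; independently, a binary
lapse label (any goal-inconsistent alcohol use that day) is recorded for every
day. Study days run from a fixed early-morning boundary (4 AM by default) to
the next day's boundary, so that late-night drinking is attributed to the
waking day on which it happened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

N_ITEMS = 9

__all__ = [
    "N_ITEMS",
    "EmaDay",
    "ParticipantSeries",
    "Cohort",
    "LapseReport",
    "make_day_labels",
    "make_window_labels",
    "compliance_filter",
    "read_cohort",
    "write_cohort",
    "read_lapse_reports",
]


@dataclass(frozen=True)
class EmaDay:
    """One study day's morning EMA: ``responses`` present iff ``observed``.

    ``responses`` is a length-9 tuple of ordinal values; individual entries may
    be None (item-level missingness within a completed survey), but the whole
    vector is None exactly when the morning EMA was not completed.
    """

    day: int
    responses: tuple | None
    observed: bool

    def __post_init__(self) -> None:
        if self.observed:
            if self.responses is None or len(self.responses) != N_ITEMS:
                raise ValueError(
                    f"day {self.day}: observed EMA must carry {N_ITEMS} responses"
                )
        elif self.responses is not None:
            raise ValueError(f"day {self.day}: responses present but observed=False")


@dataclass
class ParticipantSeries:
    """One participant's daily EMA records and fully-observed lapse vector."""

    participant_id: str
    study_length: int
    start_weekday: int
    ema: list[EmaDay]
    lapse: np.ndarray

    def __post_init__(self) -> None:
        if self.study_length < 1:
            raise ValueError("study_length must be >= 1")
        if not 0 <= self.start_weekday <= 6:
            raise ValueError("start_weekday must be in 0..6")
        if len(self.ema) != self.study_length:
            raise ValueError("need exactly one EmaDay per study day")
        if [e.day for e in self.ema] != list(range(1, self.study_length + 1)):
            raise ValueError("EMA records must cover days 1..T in order")
        self.lapse = np.asarray(self.lapse, dtype=int)
        if self.lapse.shape != (self.study_length,):
            raise ValueError("lapse vector must have length T")
        if not np.isin(self.lapse, (0, 1)).all():
            raise ValueError("lapse entries must be 0/1")

    # -- convenience views -------------------------------------------------
    def ema_matrix(self) -> np.ndarray:
        """(T, 9) float array of raw ordinal responses, NaN where missing."""
        out = np.full((self.study_length, N_ITEMS), np.nan)
        for t, rec in enumerate(self.ema):
            if rec.observed:
                out[t] = [np.nan if v is None else float(v) for v in rec.responses]
        return out

    def observed_mask(self) -> np.ndarray:
        return np.array([rec.observed for rec in self.ema], dtype=bool)

    @property
    def adherence(self) -> float:
        return float(self.observed_mask().mean())


@dataclass
class Cohort:
    participants: list[ParticipantSeries]
    ordinal_scale: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant_ids must be unique")
        lo, hi = self.ordinal_scale
        if hi <= lo:
            raise ValueError("ordinal_scale must be (min, max) with max > min")
        for p in self.participants:
            for rec in p.ema:
                if rec.observed:
                    for v in rec.responses:
                        if v is not None and not lo <= v <= hi:
                            raise ValueError(
                                f"{p.participant_id} day {rec.day}: response {v} "
                                f"outside ordinal scale {self.ordinal_scale}"
                            )

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self) -> Iterator[ParticipantSeries]:
        return iter(self.participants)

    def get(self, participant_id: str) -> ParticipantSeries:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    def subset(self, ids: Iterable[str]) -> "Cohort":
        ids = set(ids)
        return Cohort(
            [p for p in self.participants if p.participant_id in ids],
            self.ordinal_scale,
        )

    def scale01(self, values: np.ndarray) -> np.ndarray:
        """Rescale ordinal responses to [0, 1] as (r - min) / (max - min)."""
        lo, hi = self.ordinal_scale
        return (np.asarray(values, dtype=float) - lo) / (hi - lo)


@dataclass(frozen=True)
class LapseReport:
    participant_id: str
    timestamp: datetime


def make_day_labels(
    reports: Sequence[LapseReport],
    study_start: date,
    study_length: int,
    boundary_hour: float = 4.0,
) -> np.ndarray:
    """Convert timestamped drinking reports to daily binary labels.

    Study day ``t`` covers the half-open interval
    ``[start + (t-1) days + boundary, start + t days + boundary)`` so a report
    at, say, 2 AM belongs to the previous waking day, while one exactly at the
    boundary opens the new day. ``boundary_hour`` is a clock hour (4.0 default;
    3.5 encodes a 3:30 AM boundary for early risers).

    Reports after the last interval are discarded with a warning; a report
    before the day-1 boundary is rejected outright.
    """
    if study_length < 0:
        raise ValueError("study_length must be non-negative")
    start = datetime(study_start.year, study_start.month, study_start.day) + timedelta(
        hours=boundary_hour
    )
    labels = np.zeros(study_length, dtype=int)
    n_discarded = 0
    for rep in reports:
        delta = rep.timestamp - start
        if delta < timedelta(0):
            raise ValueError(
                f"report for {rep.participant_id} at {rep.timestamp} precedes "
                f"the study start boundary {start}"
            )
        day = delta.days + 1  # floor division of a non-negative timedelta
        if day > study_length:
            n_discarded += 1
            continue
        labels[day - 1] = 1
    if n_discarded:
        warnings.warn(
            f"discarded {n_discarded} report(s) after the study period",
            stacklevel=2,
        )
    return labels


def make_window_labels(lapse: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Label day ``t`` by any lapse in days ``t..t+k``; emit only eligible days.

    A day is eligible when the whole window fits in the study period
    (``t + k <= T``), so e.g. 7-day windows in a 90-day study stop at day 83.
    """
    if k < 0:
        raise ValueError("window length k must be >= 0")
    lapse = np.asarray(lapse, dtype=int)
    T = lapse.shape[0]
    return [
        (t, int(lapse[t - 1 : t + k].max())) for t in range(1, T - k + 1)
    ]


def compliance_filter(
    cohort: Cohort, threshold: float = 0.25
) -> tuple[Cohort, list[str]]:
    """Drop participants who completed fewer than ``threshold`` of morning EMAs."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    kept, excluded = [], []
    for p in cohort:
        if p.adherence >= threshold:
            kept.append(p)
        else:
            excluded.append(p.participant_id)
    return Cohort(kept, cohort.ordinal_scale), excluded


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_ITEM_COLS = [f"item_{i}" for i in range(1, N_ITEMS + 1)]


def write_cohort(cohort: Cohort, path) -> None:
    """Write the long-format cohort CSV (one row per participant-day).

    Columns: participant_id, day, item_1..item_9, lapse, start_weekday.
    Missing items are empty cells; rows are sorted by (participant, day).
    """
    rows = []
    for p in cohort.participants:
        for rec in p.ema:
            row = {"participant_id": p.participant_id, "day": rec.day}
            for j, col in enumerate(_ITEM_COLS):
                if rec.observed and rec.responses[j] is not None:
                    row[col] = rec.responses[j]
                else:
                    row[col] = pd.NA
            row["lapse"] = int(p.lapse[rec.day - 1])
            row["start_weekday"] = p.start_weekday
            rows.append(row)
    df = pd.DataFrame(rows).sort_values(["participant_id", "day"])
    df.to_csv(path, index=False)


def read_cohort(path, ordinal_scale: tuple[int, int] = (1, 5)) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-built).

    A day counts as observed iff at least one of the nine item cells is
    non-empty. Duplicate (participant, day) rows and lapse values outside
    {0, 1} are errors. ``start_weekday`` is optional (defaults to 0).
    """
    df = pd.read_csv(path)
    required = ["participant_id", "day", *_ITEM_COLS, "lapse"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    if df.duplicated(["participant_id", "day"]).any():
        dup = df[df.duplicated(["participant_id", "day"])].iloc[0]
        raise ValueError(
            f"duplicate row for participant {dup['participant_id']} day {dup['day']}"
        )
    if not df["lapse"].isin([0, 1]).all():
        raise ValueError("lapse values must be 0 or 1")
    participants = []
    for pid, grp in df.sort_values(["participant_id", "day"]).groupby(
        "participant_id", sort=True
    ):
        days = grp["day"].to_numpy()
        T = int(days.max())
        if set(days) != set(range(1, T + 1)):
            raise ValueError(f"participant {pid}: days must cover 1..T")
        ema = []
        lapse = np.zeros(T, dtype=int)
        for _, row in grp.iterrows():
            vals = [row[c] for c in _ITEM_COLS]
            observed = any(pd.notna(v) for v in vals)
            if observed:
                resp = tuple(None if pd.isna(v) else int(v) for v in vals)
            else:
                resp = None
            ema.append(EmaDay(day=int(row["day"]), responses=resp, observed=observed))
            lapse[int(row["day"]) - 1] = int(row["lapse"])
        sw = int(grp["start_weekday"].iloc[0]) if "start_weekday" in grp else 0
        participants.append(
            ParticipantSeries(
                participant_id=str(pid),
                study_length=T,
                start_weekday=sw,
                ema=ema,
                lapse=lapse,
            )
        )
    return Cohort(participants, ordinal_scale)


def read_lapse_reports(path) -> list[LapseReport]:
    """Read timestamped drinking reports: CSV(participant_id, timestamp ISO-8601)."""
    df = pd.read_csv(path)
    return [
        LapseReport(str(r["participant_id"]), datetime.fromisoformat(str(r["timestamp"])))
        for _, r in df.iterrows()
    ]
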