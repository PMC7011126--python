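"""Behavioral feature extraction from campus card-swipe event logs.

One card event is a timestamped transaction (canteen payment, dormitory door
swipe, library gate, water dispenser).  Features are computed per student
and split by festival vs nonfestival days (statutory holidays; ordinary
weekends count as nonfestival):

* meal habits — for each day and meal window, the first canteen swipe in the
  window counts as that meal; counts, mean time and SD of time (decimal
  hours, n-1 denominator) are derived per meal type;
* daily routine — counts of dormitory entries (R) and exits (O) per
  hour-of-day bin, e.g. ``"8-9 R"`` or ``"14-15 R festival"``;
* social frequency — R_ij counts all cross-pairs of canteen swipe times of
  students i and j within T seconds (default 250 s), restricted to a social
  observation window; TOP_1..TOP_5 are the five largest entries of each
  student's row and proxy the strength of their closest meal-time ties;
* academic, library, consumption and subsidy features.

Statistics undefined on fewer than two observations are emitted as missing
(NaN) and dropped pairwise downstream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Calendar",
    "MealWindows",
    "SocialMatrix",
    "assign_meals",
    "meal_features",
    "routine_features",
    "social_frequency_matrix",
    "top_k_social",
    "academic_features",
    "misc_features",
    "build_feature_table",
    "MEAL_NAMES",
    "GRADE_LEVELS",
]

MEAL_NAMES = ("breakfast", "lunch", "dinner")
GRADE_LEVELS = ("excellent", "good", "average", "pass", "fail")

_MEAL_LABEL = {"breakfast": "breakfast", "lunch": "lunche", "dinner": "dinner"}


class FeatureError(ValueError):
    """Raised for malformed event logs or invalid feature parameters."""


@dataclass(frozen=True)
class Calendar:
    """Observation window, festival dates and the social-feature subwindow."""

    observation_start: dt.date
    observation_end: dt.date
    festival_dates: frozenset = frozenset()
    social_start: dt.date | None = None
    social_end: dt.date | None = None

    def __post_init__(self) -> None:
        if self.observation_start >= self.observation_end:
            raise FeatureError("observation_start must precede observation_end")
        s = self.social_start or self.observation_start
        e = self.social_end or self.observation_end
        if not (self.observation_start <= s <= e <= self.observation_end):
            raise FeatureError("social window must lie inside the observation window")
        object.__setattr__(self, "social_start", s)
        object.__setattr__(self, "social_end", e)

    def is_festival(self, day: dt.date) -> bool:
        return day in self.festival_dates


@dataclass(frozen=True)
class MealWindows:
    """Half-open daily meal windows as (start, end) decimal hours.

    Defaults bracket typical Chinese campus canteen hours: breakfast
    05:00-10:00, lunch 10:30-15:00, dinner 16:00-21:00.
    """

    breakfast_hours: tuple[float, float] = (5.0, 10.0)
    lunch_hours: tuple[float, float] = (10.5, 15.0)
    dinner_hours: tuple[float, float] = (16.0, 21.0)

    def __post_init__(self) -> None:
        wins = [self.breakfast_hours, self.lunch_hours, self.dinner_hours]
        for lo, hi in wins:
            if not 0 <= lo < hi <= 24:
                raise FeatureError(f"invalid meal window ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(wins, wins[1:]):
            if hi > lo2:
                raise FeatureError("meal windows must be ordered and non-overlapping")

    def window(self, meal: str) -> tuple[float, float]:
        return getattr(self, f"{meal}_hours")


@dataclass(frozen=True)
class SocialMatrix:
    """Symmetric co-swipe count matrix over an ordered student list."""

    ids: tuple[str, ...]
    R: np.ndarray
    window_T: float

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.R.shape != (n, n):
            raise FeatureError("R shape must match number of ids")


def _decimal_hours(ts: pd.Series) -> pd.Series:
    t = pd.to_datetime(ts)
    return t.dt.hour + t.dt.minute / 60.0 + t.dt.second / 3600.0 + t.dt.microsecond / 3.6e9


def assign_meals(events: pd.DataFrame, windows: MealWindows | None = None) -> pd.DataFrame:
    """Assign canteen swipes to at most one meal per student, day and window.

    The meal time is the FIRST swipe falling in the (half-open) window that
    day; swipes outside every window are ignored.

    Returns a frame with columns ``student_id``, ``date``, ``meal``,
    ``time_hours``.
    """
    windows = windows or MealWindows()
    canteen = events[events["venue"] == "canteen"] if "venue" in events.columns else events
    if canteen.empty:
        return pd.DataFrame(columns=["student_id", "date", "meal", "time_hours"])
    ts = pd.to_datetime(canteen["timestamp"])
    hours = _decimal_hours(canteen["timestamp"])
    frames = []
    for meal in MEAL_NAMES:
        lo, hi = windows.window(meal)
        sel = (hours >= lo) & (hours < hi)
        if not sel.any():
            continue
        sub = pd.DataFrame(
            {
                "student_id": canteen.loc[sel, "student_id"].to_numpy(),
                "date": ts[sel].dt.date.to_numpy(),
                "meal": meal,
                "time_hours": hours[sel].to_numpy(),
            }
        )
        first = sub.groupby(["student_id", "date"], as_index=False)["time_hours"].min()
        first["meal"] = meal
        frames.append(first)
    if not frames:
        return pd.DataFrame(columns=["student_id", "date", "meal", "time_hours"])
    out = pd.concat(frames, ignore_index=True)
    return out[["student_id", "date", "meal", "time_hours"]]


def meal_features(meals: pd.DataFrame, calendar: Calendar, ids=None) -> pd.DataFrame:
    """Per-student meal counts and nonfestival time statistics.

    Columns follow the published row labels: ``Number of breakfasts``,
    ``Number of breakfasts during festival``, ``Breakfast Time`` (nonfestival
    mean in decimal hours), ``SD of time of breakfast`` (sample SD, missing
    when fewer than two records), and the lunch/dinner analogues.
    """
    if ids is None:
        ids = sorted(meals["student_id"].unique()) if not meals.empty else []
    out = pd.DataFrame(index=pd.Index(ids, name="student_id"))
    if meals.empty:
        festival = pd.Series(dtype=bool)
    else:
        festival = meals["date"].map(calendar.is_festival)
    for meal in MEAL_NAMES:
        label = _MEAL_LABEL[meal]
        cap = meal.capitalize()
        if meals.empty:
            nf = f_ = meals
        else:
            m = meals["meal"] == meal
            nf = meals[m & ~festival]
            f_ = meals[m & festival]
        grp = nf.groupby("student_id")["time_hours"] if not nf.empty else None
        out[f"Number of {label}s"] = (
            grp.size().reindex(ids, fill_value=0) if grp is not None else 0
        )
        out[f"Number of {label}s during festival"] = (
            f_.groupby("student_id").size().reindex(ids, fill_value=0) if not f_.empty else 0
        )
        if grp is not None:
            mean = grp.mean()
            sd = grp.std(ddof=1)  # NaN for singletons
            count = grp.size()
            mean = mean.where(count >= 2)
        else:
            mean = sd = pd.Series(dtype=float)
        out[f"{cap} Time"] = mean.reindex(ids)
        out[f"SD of time of {meal}"] = sd.reindex(ids) if grp is not None else np.nan
    return out


def _hour_label(h: int) -> str:
    return f"{h}-{h + 1}"


def routine_features(events: pd.DataFrame, calendar: Calendar, ids=None) -> pd.DataFrame:
    """Hourly dormitory entry/exit counts split by festival vs nonfestival.

    Column names: ``"8-9 R"``, ``"8-9 O"``, ``"8-9 R festival"``, ... where R
    is returning to (direction ``in``) and O leaving (``out``) the dormitory.
    Hour bins are half-open [h, h+1) on the local wall clock.
    """
    dorm = events[events["venue"] == "dorm_door"] if "venue" in events.columns else events
    if not dorm.empty and dorm["direction"].isin(["in", "out"]).sum() != len(dorm):
        bad = dorm[~dorm["direction"].isin(["in", "out"])].iloc[0]
        raise FeatureError(f"dorm event without direction for student {bad['student_id']!r}")
    if ids is None:
        ids = sorted(dorm["student_id"].unique()) if not dorm.empty else []
    cols = []
    for fest in ("", " festival"):
        for h in range(24):
            for d in ("R", "O"):
                cols.append(f"{_hour_label(h)} {d}{fest}")
    out = pd.DataFrame(0, index=pd.Index(ids, name="student_id"), columns=cols)
    if dorm.empty:
        return out
    ts = pd.to_datetime(dorm["timestamp"])
    hour = ts.dt.hour
    fest = ts.dt.date.map(calendar.is_festival)
    dirlab = dorm["direction"].map({"in": "R", "out": "O"})
    lab = (
        hour.astype(str)
        + "-"
        + (hour + 1).astype(str)
        + " "
        + dirlab
        + np.where(fest, " festival", "")
    )
    counts = (
        pd.DataFrame({"student_id": dorm["student_id"].to_numpy(), "col": lab.to_numpy()})
        .groupby(["student_id", "col"])
        .size()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(index=ids, columns=cols, fill_value=0).fillna(0).astype(int)
    counts.index.name = "student_id"
    return counts


def social_frequency_matrix(
    events: pd.DataFrame,
    T: float = 250.0,
    ids=None,
    start: dt.date | None = None,
    end: dt.date | None = None,
) -> SocialMatrix:
    """Meal-time co-occurrence matrix R from canteen swipe times.

    ``R[i, j]`` counts every cross-pair of swipe times (S_im, S_jn) of
    students i != j with ``|S_im - S_jn| <= T`` seconds (closed window); it
    equals the naive double loop over all swipe pairs.  ``start``/``end``
    restrict events to the social observation window (inclusive dates).
    """
    if T <= 0:
        raise FeatureError("co-swipe window T must be positive")
    canteen = events[events["venue"] == "canteen"] if "venue" in events.columns else events
    ts = pd.to_datetime(canteen["timestamp"])
    if start is not None:
        keep = ts.dt.date >= start
        canteen, ts = canteen[keep], ts[keep]
    if end is not None:
        keep = ts.dt.date <= end
        canteen, ts = canteen[keep], ts[keep]
    if ids is None:
        ids = sorted(canteen["student_id"].unique())
    ids = tuple(ids)
    n = len(ids)
    if n < 2:
        raise FeatureError("social matrix requires at least 2 students")
    R = np.zeros((n, n), dtype=np.int64)
    if canteen.empty:
        return SocialMatrix(ids=ids, R=R, window_T=float(T))
    idx = {s: k for k, s in enumerate(ids)}
    owner = canteen["student_id"].map(idx).to_numpy()
    known = ~pd.isna(owner)
    owner = owner[known].astype(np.int64)
    t = (ts.astype("int64").to_numpy()[known] / 1e9).astype(np.float64)
    order = np.argsort(t, kind="stable")
    t, owner = t[order], owner[order]
    m = len(t)
    # for each event k, events k+1 .. right[k]-1 are within T seconds after it
    right = np.searchsorted(t, t + T, side="right")
    lengths = right - np.arange(m) - 1
    total = int(lengths.sum())
    if total:
        starts = np.arange(m) + 1
        offs = np.arange(total) - np.repeat(np.concatenate([[0], np.cumsum(lengths)[:-1]]), lengths)
        j_idx = np.repeat(starts, lengths) + offs
        i_own = np.repeat(owner, lengths)
        j_own = owner[j_idx]
        keep = i_own != j_own  # self-pairs never counted
        codes = i_own[keep] * n + j_own[keep]
        counts = np.bincount(codes, minlength=n * n).reshape(n, n)
        R = counts + counts.T
    return SocialMatrix(ids=ids, R=R, window_T=float(T))


def top_k_social(matrix: SocialMatrix, k: int = 5) -> pd.DataFrame:
    """TOP_1..TOP_k: each student's k largest off-diagonal row entries.

    Rows with fewer than k other students are zero-padded; ties are
    preserved by value.
    """
    if k < 1:
        raise FeatureError("k must be at least 1")
    n = len(matrix.ids)
    R = matrix.R.astype(float).copy()
    np.fill_diagonal(R, -np.inf)
    srt = -np.sort(-R, axis=1)[:, : min(k, n - 1)]
    srt[~np.isfinite(srt)] = 0.0
    if srt.shape[1] < k:
        srt = np.pad(srt, ((0, 0), (0, k - srt.shape[1])))
    cols = [f"TOP_{m}" for m in range(1, k + 1)]
    return pd.DataFrame(srt, index=pd.Index(matrix.ids, name="student_id"), columns=cols)


def academic_features(grades: pd.DataFrame, ids=None) -> pd.DataFrame:
    """Counts per exam level plus excellent/fail rates.

    ``grades`` is long-format with columns ``student_id`` and ``level`` (one
    row per graded course, level in excellent/good/average/pass/fail).
    Rates are missing for students with zero graded courses.
    """
    if not grades.empty:
        bad = set(grades["level"].unique()) - set(GRADE_LEVELS)
        if bad:
            raise FeatureError(f"unknown grade levels: {sorted(bad)}")
    if ids is None:
        ids = sorted(grades["student_id"].unique()) if not grades.empty else []
    out = pd.DataFrame(index=pd.Index(ids, name="student_id"))
    if grades.empty:
        counts = pd.DataFrame(0, index=out.index, columns=list(GRADE_LEVELS))
    else:
        counts = (
            grades.groupby(["student_id", "level"]).size().unstack(fill_value=0)
        ).reindex(index=ids, columns=list(GRADE_LEVELS), fill_value=0)
    for lev in GRADE_LEVELS:
        out[f"Number of {lev}"] = counts[lev].astype(int)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["Excellent rate"] = np.where(total > 0, counts["excellent"] / total, np.nan)
        out["Fail rate"] = np.where(total > 0, counts["fail"] / total, np.nan)
    return out


_ROSTER_PASSTHROUGH = {
    "n_subsidy_applications": "Number of subsidy applications",
    "subsidy_this_year": "Applied subsidy this year",
    "scholarship_total_amount": "Scholarship total amount",
    "scholarship_last_year_amount": "Scholarship last year amount",
    "n_scholarships": "Number of scholarships",
    "total_books_borrowed": "Total books borrowed",
    "semester_books_borrowed": "Semester books borrowed",
}


def misc_features(events: pd.DataFrame, roster: pd.DataFrame, ids=None) -> pd.DataFrame:
    """Library, consumption, water-intake and roster pass-through features.

    Monthly consumption summarises per-calendar-month total spend with
    {mean, SD, min, max, total, count}; weekly spend with {mean, SD, min,
    max}.  Water intake is the count of water-dispenser transactions.
    """
    if ids is None:
        ids = sorted(roster["student_id"].unique())
    out = pd.DataFrame(index=pd.Index(ids, name="student_id"))
    if not events.empty and (pd.to_numeric(events["amount"], errors="coerce") < 0).any():
        raise FeatureError("negative transaction amounts in event log")
    lib = events[events["venue"] == "library"] if not events.empty else events
    out["Number of library visits"] = (
        lib.groupby("student_id").size().reindex(ids, fill_value=0) if not lib.empty else 0
    )
    water = events[events["venue"] == "water"] if not events.empty else events
    out["Water intake"] = (
        water.groupby("student_id").size().reindex(ids, fill_value=0) if not water.empty else 0
    )
    spend = events[events["amount"] > 0] if not events.empty else events
    if not spend.empty:
        ts = pd.to_datetime(spend["timestamp"])
        monthly = (
            spend.assign(period=ts.dt.to_period("M"))
            .groupby(["student_id", "period"], observed=True)["amount"]
            .sum()
        )
        weekly = (
            spend.assign(period=ts.dt.to_period("W"))
            .groupby(["student_id", "period"], observed=True)["amount"]
            .sum()
        )
    else:
        monthly = weekly = pd.Series(dtype=float)

    def _summary(series: pd.Series, prefix: str, stats: tuple[str, ...]) -> None:
        if series.empty:
            for s in stats:
                out[f"{prefix} {s}"] = np.nan if s not in ("count", "total") else 0
            return
        g = series.groupby(level="student_id")
        fns = {
            "mean": g.mean(),
            "SD": g.std(ddof=1),
            "min": g.min(),
            "max": g.max(),
            "total": g.sum(),
            "count": g.size(),
        }
        for s in stats:
            col = fns[s].reindex(ids)
            if s in ("count", "total"):
                col = col.fillna(0)
            out[f"{prefix} {s}"] = col

    _summary(monthly, "Monthly consumption", ("mean", "SD", "min", "max", "total", "count"))
    _summary(weekly, "Weekly consumption", ("mean", "SD", "min", "max"))
    ros = roster.set_index("student_id")
    for src, dst in _ROSTER_PASSTHROUGH.items():
        if src in ros.columns:
            out[dst] = ros[src].reindex(ids)
    return out


def build_feature_table(
    events: pd.DataFrame,
    roster: pd.DataFrame,
    calendar: Calendar,
    grades: pd.DataFrame | None = None,
    windows: MealWindows | None = None,
    T: float = 250.0,
    k: int = 5,
) -> pd.DataFrame:
    """Assemble the full per-student behavioral feature table."""
    windows = windows or MealWindows()
    ids = sorted(roster["student_id"].unique())
    meals = assign_meals(events, windows)
    parts = [
        meal_features(meals, calendar, ids=ids),
        routine_features(events, calendar, ids=ids),
        misc_features(events, roster, ids=ids),
    ]
    if len(ids) >= 2:
        sm = social_frequency_matrix(
            events, T=T, ids=ids, start=calendar.social_start, end=calendar.social_end
        )
        parts.append(top_k_social(sm, k=k))
    if grades is not None:
        parts.append(academic_features(grades, ids=ids))
    return pd.concat(parts, axis=1)
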