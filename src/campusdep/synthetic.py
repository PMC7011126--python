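"""Synthetic campus cohort generator.

The study data (card-swipe logs and questionnaires of a real student
cohort) are private, so this module generates a cohort with the same
statistical structure, making every downstream stage testable:

* a roster of ~466 students with ~25% depression prevalence (severity split
  mild/moderate/severe roughly 16/6/3 percentage points);
* 20-item SDS responses drawn from a planted 4-factor model (correlated
  latent factors -> loadings -> a latent normal discretised to the 1-4
  Likert scale), with severity-dependent mean shifts so the scored SDS
  tracks the latent label;
* BDI responses and completion durations consistent with the SDS label;
* a semester of card events (canteen meals, dormitory door swipes, library
  gates, water dispensers) in which latently depressed students eat later
  and less often, show elevated 20:00-24:00 and reduced 06:00-10:00
  dormitory activity, and synchronise meals with friends less often;
* meal-time co-occurrence induced by a random friendship graph (mean degree
  3) whose members share meal events with jittered offsets within +/-120 s,
  guaranteeing nonzero co-swipe counts under a 250 s window.

Three independent pseudo-random streams (questionnaire, events, graph) are
derived from the master seed, so output is byte-identical for a fixed seed
and stable when one domain's generation logic changes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import Calendar, MEAL_NAMES
from .questionnaire import REVERSE_KEYED_ITEMS, DEFAULT_ITEM_TO_FACTOR

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "default_effect_sizes",
    "zero_effect_sizes",
    "default_loading_matrix",
    "generate_cohort",
    "generate_sds_items",
    "write_cohort",
    "read_cohort",
    "ParseError",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


class ParseError(ValueError):
    """Raised when a cohort CSV contains a malformed or out-of-range row."""


# --- planted questionnaire model constants ---------------------------------
#: Likert discretisation thresholds on the latent normal item score.
LIKERT_THRESHOLDS = (0.2, 1.0, 1.8)
#: Latent factor mean shift per severity (none, mild, moderate, severe).
SEVERITY_SHIFTS = (0.0, 1.0, 1.3, 1.6)
#: Correlation between latent factors (oblique structure).
FACTOR_CORRELATION = 0.3
#: Severity mix within the depressed fraction (mild, moderate, severe).
SEVERITY_MIX = (0.6441, 0.2543, 0.1016)

SEVERITY_LABELS = ("none", "mild", "moderate", "severe")

# --- behavioral base rates (nondepressed) ----------------------------------
MEAL_ATTEND_P = {"breakfast": 0.44, "lunch": 0.60, "dinner": 0.54}
MEAL_MEAN_HOURS = {"breakfast": 7.7, "lunch": 11.75, "dinner": 17.47}
MEAL_SD_HOURS = {"breakfast": 0.70, "lunch": 0.55, "dinner": 0.60}
FESTIVAL_MEAL_FACTOR = 0.75  # students leave campus / sleep in on holidays
FESTIVAL_DORM_FACTOR = 1.2

#: Dormitory door events per hour per day (entries + exits combined).
DORM_HOURLY_RATE = np.array(
    [
        0.010, 0.004, 0.002, 0.002, 0.002, 0.004,  # 0-5
        0.020, 0.045, 0.053, 0.079, 0.052, 0.030,  # 6-11
        0.045, 0.067, 0.035, 0.035, 0.045, 0.060,  # 12-17
        0.070, 0.060, 0.130, 0.136, 0.104, 0.065,  # 18-23
    ]
)

FRIEND_SYNC_P = 0.65  # chance a co-attending friend pair aligns a meal
SYNC_JITTER_SECONDS = 120.0

_SDS_COLS = [f"q{i}" for i in range(1, 21)]
_BDI_COLS = [f"b{i}" for i in range(1, 22)]


def default_effect_sizes() -> dict[str, float]:
    """Behavioral contrasts applied to the latently depressed group."""
    return {
        "meal_time_shift_hours": 0.12,
        "meal_skip_delta": 0.055,
        "breakfast_sd_multiplier": 1.10,
        "evening_rate_multiplier": 1.5,
        "morning_rate_multiplier": 0.6,
        "codining_multiplier": 0.7,
    }


def zero_effect_sizes() -> dict[str, float]:
    """Neutral effects: the two latent groups behave identically (null model)."""
    return {
        "meal_time_shift_hours": 0.0,
        "meal_skip_delta": 0.0,
        "breakfast_sd_multiplier": 1.0,
        "evening_rate_multiplier": 1.0,
        "morning_rate_multiplier": 1.0,
        "codining_multiplier": 1.0,
    }


#: Secondary (cross) loadings planted alongside the primary structure,
#: (item, factor-index, value).  The diurnal-variation factor borrows
#: variance from appetite/devaluation/emptiness/constipation items, which is
#: what keeps its correlation-matrix eigenvalue above the Kaiser threshold
#: despite having a single primary item.
CROSS_LOADINGS = (
    (5, 3, -0.46),
    (8, 3, -0.40),
    (17, 3, 0.36),
    (18, 3, 0.36),
    (9, 1, 0.379),
    (6, 1, 0.263),
)


def default_loading_matrix(
    primary: float = 0.75, singleton: float = 0.9, cross: bool = True
) -> np.ndarray:
    """20x4 planted loading matrix following the four-symptom grouping.

    Each item loads primarily on one factor (the single-item diurnal factor
    gets a higher loading); with ``cross=True`` the secondary loadings in
    :data:`CROSS_LOADINGS` are added.
    """
    L = np.zeros((20, 4))
    fidx = {"F1": 0, "F2": 1, "F3": 2, "F4": 3}
    for item, fac in DEFAULT_ITEM_TO_FACTOR.items():
        L[item - 1, fidx[fac]] = singleton if fac == "F4" else primary
    if cross:
        for item, j, v in CROSS_LOADINGS:
            L[item - 1, j] = v
    return L


def _default_festivals() -> frozenset:
    return frozenset(
        {dt.date(2017, 10, d) for d in range(2, 7)} | {dt.date(2018, 1, 1)}
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for the synthetic cohort."""

    n_students: int = 466
    depression_prevalence: float = 0.2532
    factor_loading_matrix: np.ndarray = field(default_factory=default_loading_matrix)
    effect_sizes: dict = field(default_factory=default_effect_sizes)
    semester_start: dt.date = dt.date(2017, 9, 11)
    semester_end: dt.date = dt.date(2018, 1, 10)
    social_start: dt.date = dt.date(2017, 11, 20)
    festival_dates: frozenset = field(default_factory=_default_festivals)
    mean_degree: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_students < 2:
            raise ConfigurationError("n_students must be at least 2")
        if not 0.0 <= self.depression_prevalence <= 1.0:
            raise ConfigurationError("depression_prevalence must lie in [0, 1]")
        if self.semester_start >= self.semester_end:
            raise ConfigurationError("semester_start must precede semester_end")
        L = np.asarray(self.factor_loading_matrix, dtype=float)
        if L.shape != (20, 4) or not np.isfinite(L).all():
            raise ConfigurationError("factor_loading_matrix must be a finite 20x4 matrix")
        missing = set(default_effect_sizes()) - set(self.effect_sizes)
        if missing:
            raise ConfigurationError(f"effect_sizes missing keys: {sorted(missing)}")

    def calendar(self) -> Calendar:
        start = max(self.social_start, self.semester_start)
        return Calendar(
            observation_start=self.semester_start,
            observation_end=self.semester_end,
            festival_dates=frozenset(self.festival_dates),
            social_start=min(start, self.semester_end),
            social_end=self.semester_end,
        )


@dataclass
class SyntheticCohort:
    """Generated roster, event log, questionnaires and ground-truth labels."""

    roster: pd.DataFrame
    card_events: pd.DataFrame
    sds: pd.DataFrame
    bdi: pd.DataFrame
    latent_status: pd.Series
    calendar: Calendar

    def equals(self, other: "SyntheticCohort") -> bool:
        try:
            pd.testing.assert_frame_equal(self.roster, other.roster)
            pd.testing.assert_frame_equal(self.card_events, other.card_events)
            pd.testing.assert_frame_equal(self.sds, other.sds)
            pd.testing.assert_frame_equal(self.bdi, other.bdi)
            pd.testing.assert_series_equal(self.latent_status, other.latent_status)
        except AssertionError:
            return False
        return self.calendar == other.calendar


# ---------------------------------------------------------------------------
# Questionnaire generation
# ---------------------------------------------------------------------------

def generate_sds_items(
    status_idx: np.ndarray,
    loadings: np.ndarray,
    rng: np.random.Generator,
    thresholds: tuple[float, float, float] = LIKERT_THRESHOLDS,
    shifts: tuple[float, ...] = SEVERITY_SHIFTS,
    factor_corr: float = FACTOR_CORRELATION,
) -> np.ndarray:
    """Keyed 1-4 item intensities from the planted oblique factor model.

    Latent factor scores (equicorrelated, severity-shifted) are mapped
    through the loading matrix, unit-variance noise is added, and the
    resulting latent normal is cut at fixed thresholds.  Returns the (n, 20)
    symptom-intensity matrix ``c`` (1..4); the recorded response of a
    reverse-keyed item is ``5 - c``.
    """
    n = len(status_idx)
    L = np.asarray(loadings, dtype=float)
    phi = np.full((4, 4), factor_corr) + (1 - factor_corr) * np.eye(4)
    chol = np.linalg.cholesky(phi)
    eta = rng.standard_normal((n, 4)) @ chol.T
    eta += np.asarray(shifts)[status_idx][:, None]
    common_var = np.einsum("if,fg,ig->i", L, phi, L)
    unique_sd = np.sqrt(np.clip(1.0 - common_var, 0.05, None))
    y = eta @ L.T + rng.standard_normal((n, 20)) * unique_sd[None, :]
    c = np.ones((n, 20), dtype=np.int64)
    for t in thresholds:
        c += y > t
    return c


def _responses_from_intensity(c: np.ndarray) -> np.ndarray:
    rev = np.array([i in REVERSE_KEYED_ITEMS for i in range(1, 21)])
    return np.where(rev[None, :], 5 - c, c)


def _generate_questionnaires(status_idx, config: CohortConfig, rng):
    n = len(status_idx)
    c = generate_sds_items(status_idx, config.factor_loading_matrix, rng)
    responses = _responses_from_intensity(c)
    durations = np.round(rng.lognormal(np.log(420.0), 0.45, n), 1)
    bdi_p = np.array([0.05, 0.18, 0.28, 0.38])[status_idx]
    bdi_p = np.clip(bdi_p + 0.03 * rng.standard_normal(n), 0.01, 0.9)
    bdi = rng.binomial(3, bdi_p[:, None], (n, 21))
    return responses, durations, bdi


# ---------------------------------------------------------------------------
# Event generation
# ---------------------------------------------------------------------------

def _friendship_edges(n: int, mean_degree: float, rng) -> np.ndarray:
    p = min(1.0, mean_degree / max(n - 1, 1))
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < p
    return np.column_stack([iu[keep], ju[keep]])


def _generate_meals(dep: np.ndarray, days_fest: np.ndarray, config, rng, edges):
    """Attendance (n, D, 3) and swipe times in decimal hours, NaN if skipped."""
    eff = config.effect_sizes
    n, D = len(dep), len(days_fest)
    attend = np.zeros((n, D, 3), dtype=bool)
    times = np.full((n, D, 3), np.nan)
    for mi, meal in enumerate(MEAL_NAMES):
        p = MEAL_ATTEND_P[meal] - eff["meal_skip_delta"] * dep
        p = np.clip(p[:, None] * np.where(days_fest, FESTIVAL_MEAL_FACTOR, 1.0)[None, :], 0, 1)
        attend[:, :, mi] = rng.random((n, D)) < p
        mu = MEAL_MEAN_HOURS[meal] + eff["meal_time_shift_hours"] * dep
        sd = np.full(n, MEAL_SD_HOURS[meal])
        if meal == "breakfast":
            sd = sd * np.where(dep, eff["breakfast_sd_multiplier"], 1.0)
        times[:, :, mi] = rng.normal(mu[:, None], sd[:, None], (n, D))
    # friends who both attend a meal may synchronise their swipe times
    sync_mult = np.where(dep, eff["codining_multiplier"], 1.0)
    jit = SYNC_JITTER_SECONDS / 3600.0
    for a, b in edges:
        both = attend[a] & attend[b]
        sync = both & (rng.random((D, 3)) < FRIEND_SYNC_P * sync_mult[a] * sync_mult[b])
        if sync.any():
            k = int(sync.sum())
            # the pair settles on the midpoint of their intended times
            base = 0.5 * (times[a][sync] + times[b][sync])
            times[a][sync] = base + rng.uniform(-jit, jit, k)
            times[b][sync] = base + rng.uniform(-jit, jit, k)
    from .features import MealWindows

    w = MealWindows()
    for mi, meal in enumerate(MEAL_NAMES):
        lo, hi = w.window(meal)
        times[:, :, mi] = np.clip(times[:, :, mi], lo + 1e-3, hi - 1e-3)
    times[~attend] = np.nan
    return attend, times


def _generate_dorm_counts(dep, days_fest, config, rng):
    eff = config.effect_sizes
    n, D = len(dep), len(days_fest)
    mult = np.ones((n, 24))
    mult[dep, 20:24] = eff["evening_rate_multiplier"]
    mult[dep, 6:10] = eff["morning_rate_multiplier"]
    lam = DORM_HOURLY_RATE[None, None, :] * mult[:, None, :]
    lam = lam * np.where(days_fest, FESTIVAL_DORM_FACTOR, 1.0)[None, :, None]
    return rng.poisson(lam)


def _expand_counts(counts: np.ndarray, rng):
    """Flatten an (n, D, 24) count tensor into per-event (student, day, hour)."""
    flat = counts.ravel()
    nz = np.nonzero(flat)[0]
    reps = flat[nz]
    cells = np.repeat(nz, reps)
    n, D, H = counts.shape
    s = cells // (D * H)
    d = (cells // H) % D
    h = cells % H
    frac = rng.random(len(cells))
    return s, d, h + frac


def _generate_events(status_idx, config: CohortConfig, ids, rng_events, rng_graph):
    n = len(ids)
    dep = status_idx > 0
    days = pd.date_range(config.semester_start, config.semester_end, freq="D")
    D = len(days)
    days_fest = np.array([d.date() in config.festival_dates for d in days])
    day0 = np.datetime64(config.semester_start)

    edges = _friendship_edges(n, config.mean_degree, rng_graph)
    attend, meal_times = _generate_meals(dep, days_fest, config, rng_events, edges)

    sid = np.asarray(ids)
    recs = []

    # canteen meal payments
    s_idx, d_idx, m_idx = np.nonzero(attend)
    secs = d_idx * 86400 + np.round(meal_times[s_idx, d_idx, m_idx] * 3600).astype(np.int64)
    amounts = np.round(rng_events.lognormal(np.log(11.0), 0.35, len(s_idx)), 2)
    recs.append((s_idx, secs, "canteen", np.full(len(s_idx), "n/a", dtype=object), amounts))

    # dormitory door swipes
    counts = _generate_dorm_counts(dep, days_fest, config, rng_events)
    s_idx, d_idx, hours = _expand_counts(counts, rng_events)
    secs = d_idx * 86400 + np.round(hours * 3600).astype(np.int64)
    secs = np.minimum(secs, (d_idx + 1) * 86400 - 1)
    direction = np.where(rng_events.random(len(s_idx)) < 0.5, "in", "out").astype(object)
    recs.append((s_idx, secs, "dorm_door", direction, np.zeros(len(s_idx))))

    # library gate events
    lib_counts = rng_events.poisson(15.0, n)
    s_idx = np.repeat(np.arange(n), lib_counts)
    d_idx = rng_events.integers(0, D, len(s_idx))
    hours = rng_events.uniform(8.0, 22.0, len(s_idx))
    secs = d_idx * 86400 + np.round(hours * 3600).astype(np.int64)
    recs.append(
        (s_idx, secs, "library", np.full(len(s_idx), "n/a", dtype=object), np.zeros(len(s_idx)))
    )

    # water dispenser purchases at the dormitory
    wat_counts = rng_events.poisson(40.0, n)
    s_idx = np.repeat(np.arange(n), wat_counts)
    d_idx = rng_events.integers(0, D, len(s_idx))
    hours = rng_events.uniform(6.0, 23.5, len(s_idx))
    secs = d_idx * 86400 + np.round(hours * 3600).astype(np.int64)
    amounts = np.round(rng_events.lognormal(np.log(1.5), 0.3, len(s_idx)), 2)
    recs.append((s_idx, secs, "water", np.full(len(s_idx), "n/a", dtype=object), amounts))

    frames = []
    for s_idx, secs, venue, direction, amounts in recs:
        frames.append(
            pd.DataFrame(
                {
                    "student_id": sid[s_idx],
                    "timestamp": day0 + secs.astype("timedelta64[s]"),
                    "venue": venue,
                    "direction": direction,
                    "amount": amounts,
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    events["timestamp"] = events["timestamp"].astype("datetime64[ns]")
    events = events.sort_values(
        ["timestamp", "student_id", "venue"], kind="stable", ignore_index=True
    )
    return events


# ---------------------------------------------------------------------------
# Roster generation
# ---------------------------------------------------------------------------

_GRADE_DIST = np.array([0.459, 0.178, 0.161, 0.176, 0.021, 0.005])
_GRADE_LEVEL_P = {
    False: np.array([0.15, 0.30, 0.30, 0.20, 0.05]),
    True: np.array([0.10, 0.27, 0.30, 0.23, 0.10]),
}
_SUBSIDY_RATE = {False: 0.049, True: 0.1017}


def _generate_roster(status_idx, ids, rng) -> pd.DataFrame:
    n = len(ids)
    dep = status_idx > 0
    gender = np.where(rng.random(n) < 0.305, "F", "M")
    grade = rng.choice(np.arange(1, 7), n, p=_GRADE_DIST / _GRADE_DIST.sum())
    age = 16 + grade + rng.integers(0, 2, n)
    applied = rng.random(n) < np.where(dep, _SUBSIDY_RATE[True], _SUBSIDY_RATE[False])
    n_apps = applied * rng.integers(1, 3, n)
    this_year = (applied & (rng.random(n) < 0.7)).astype(int)
    n_sch = rng.poisson(0.5, n)
    total_amount = n_sch * 2000.0
    last_year = np.round(total_amount * rng.uniform(0, 1, n), 0)
    total_books = rng.poisson(12.0, n)
    semester_books = rng.binomial(total_books, 0.4)
    n_courses = rng.integers(8, 14, n)
    level_counts = np.zeros((n, 5), dtype=np.int64)
    for i in range(n):
        level_counts[i] = rng.multinomial(n_courses[i], _GRADE_LEVEL_P[bool(dep[i])])
    roster = pd.DataFrame(
        {
            "student_id": ids,
            "gender": gender,
            "grade": grade,
            "age": age,
            "n_subsidy_applications": n_apps.astype(int),
            "subsidy_this_year": this_year,
            "n_scholarships": n_sch,
            "scholarship_total_amount": total_amount,
            "scholarship_last_year_amount": last_year,
            "total_books_borrowed": total_books,
            "semester_books_borrowed": semester_books,
            "n_excellent": level_counts[:, 0],
            "n_good": level_counts[:, 1],
            "n_average": level_counts[:, 2],
            "n_pass": level_counts[:, 3],
            "n_fail": level_counts[:, 4],
        }
    )
    return roster


# ---------------------------------------------------------------------------
# Top-level generation and round-trip I/O
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    config = config or CohortConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    ss = np.random.SeedSequence(config.seed)
    rng_q, rng_e, rng_g = (np.random.default_rng(s) for s in ss.spawn(3))

    n = config.n_students
    ids = np.array([f"S{i:05d}" for i in range(1, n + 1)])
    prev = config.depression_prevalence
    probs = np.array([1.0 - prev, *(prev * np.asarray(SEVERITY_MIX) / sum(SEVERITY_MIX))])
    status_idx = rng_q.choice(4, size=n, p=probs / probs.sum())

    responses, durations, bdi_items = _generate_questionnaires(status_idx, config, rng_q)
    sds = pd.DataFrame(responses, columns=_SDS_COLS)
    sds.insert(0, "student_id", ids)
    sds["duration_seconds"] = durations
    bdi = pd.DataFrame(bdi_items, columns=_BDI_COLS)
    bdi.insert(0, "student_id", ids)

    events = _generate_events(status_idx, config, ids, rng_e, rng_g)
    roster = _generate_roster(status_idx, ids, rng_q)
    latent = pd.Series(
        np.asarray(SEVERITY_LABELS)[status_idx], index=pd.Index(ids, name="student_id"),
        name="latent_status",
    )
    return SyntheticCohort(
        roster=roster,
        card_events=events,
        sds=sds,
        bdi=bdi,
        latent_status=latent,
        calendar=config.calendar(),
    )


def write_cohort(cohort: SyntheticCohort, directory) -> list[Path]:
    """Write the cohort as the CSV bundle consumed by the pipeline."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    ev = cohort.card_events.copy()
    ev["timestamp"] = pd.to_datetime(ev["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    for name, frame in [
        ("roster.csv", cohort.roster),
        ("card_events.csv", ev),
        ("sds.csv", cohort.sds),
        ("bdi.csv", cohort.bdi),
        ("latent_status.csv", cohort.latent_status.reset_index()),
    ]:
        p = d / name
        frame.to_csv(p, index=False)
        paths.append(p)
    cal = cohort.calendar
    rows = [
        ("observation_start", cal.observation_start.isoformat()),
        ("observation_end", cal.observation_end.isoformat()),
        ("social_start", cal.social_start.isoformat()),
        ("social_end", cal.social_end.isoformat()),
    ] + [("festival", day.isoformat()) for day in sorted(cal.festival_dates)]
    p = d / "calendar.csv"
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(p, index=False)
    paths.append(p)
    return paths


_VENUES = {"canteen", "dorm_door", "library", "water"}


def _check_range(df: pd.DataFrame, cols, lo, hi, fname) -> None:
    vals = df[cols].to_numpy()
    bad = np.argwhere((vals < lo) | (vals > hi))
    if len(bad):
        r, c = bad[0]
        raise ParseError(
            f"{fname}, line {r + 2}: column {cols[c]} value {vals[r, c]!r} "
            f"outside [{lo}, {hi}]"
        )


def read_calendar(path) -> Calendar:
    """Read a key/value calendar CSV into a :class:`Calendar`."""
    kv = pd.read_csv(path)
    pairs = dict(zip(kv["key"], kv["value"]))
    fest = frozenset(
        dt.date.fromisoformat(v) for k, v in zip(kv["key"], kv["value"]) if k == "festival"
    )
    return Calendar(
        observation_start=dt.date.fromisoformat(pairs["observation_start"]),
        observation_end=dt.date.fromisoformat(pairs["observation_end"]),
        festival_dates=fest,
        social_start=dt.date.fromisoformat(pairs["social_start"]),
        social_end=dt.date.fromisoformat(pairs["social_end"]),
    )


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort CSV bundle back; validates ranges and vocabulary.

    Raises :class:`ParseError` naming the file and 1-based line of the first
    offending row.
    """
    d = Path(directory)
    roster = pd.read_csv(d / "roster.csv", dtype={"student_id": str})
    events = pd.read_csv(
        d / "card_events.csv",
        dtype={"student_id": str},
        keep_default_na=False,  # the direction sentinel "n/a" is a value
        na_values=[""],
    )
    if len(events):
        badv = ~events["venue"].isin(_VENUES)
        if badv.any():
            i = int(np.argmax(badv.to_numpy()))
            raise ParseError(
                f"card_events.csv, line {i + 2}: unknown venue {events['venue'].iloc[i]!r}"
            )
        events["timestamp"] = pd.to_datetime(events["timestamp"], format="%Y-%m-%dT%H:%M:%S")
        unknown = ~events["student_id"].isin(set(roster["student_id"]))
        if unknown.any():
            i = int(np.argmax(unknown.to_numpy()))
            raise ParseError(
                f"card_events.csv, line {i + 2}: student "
                f"{events['student_id'].iloc[i]!r} not in roster"
            )
    else:
        events["timestamp"] = pd.to_datetime(events["timestamp"])
    sds = pd.read_csv(d / "sds.csv", dtype={"student_id": str})
    _check_range(sds, _SDS_COLS, 1, 4, "sds.csv")
    bdi = pd.read_csv(d / "bdi.csv", dtype={"student_id": str})
    _check_range(bdi, _BDI_COLS, 0, 3, "bdi.csv")
    latent = pd.read_csv(d / "latent_status.csv", dtype={"student_id": str})
    latent = latent.set_index("student_id")["latent_status"]
    return SyntheticCohort(
        roster=roster,
        card_events=events,
        sds=sds,
        bdi=bdi,
        latent_status=latent,
        calendar=read_calendar(d / "calendar.csv"),
    )
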