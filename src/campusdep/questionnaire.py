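"""Scoring and quality control for the Zung Self-Rating Depression Scale (SDS).

The SDS is a 20-item, 4-point Likert instrument covering depressive affect
and related symptomatology over the past week (1 = rarely or none of the
time, 4 = most or all of the time).  Half of the items are worded positively
and are reverse-keyed, so a keyed contribution is ``5 - score`` for those
items.  The raw score (sum of keyed contributions) ranges 20-80 and the
standard score is ``raw * 1.25`` on a 25-100 scale, classified against the
Chinese-norm severity cutoffs (53 mild, 63 moderate, 73 severe).

Three quality-control screens mirror common practice for online
questionnaire deployments on a campus network:

* a response-time screen dropping the fastest 5% of completions,
* a cross-instrument contradiction screen against the Beck Depression
  Inventory (BDI) total, and
* an off-campus screen dropping students who never swipe for breakfast at
  the campus canteens.

Factor (symptom-group) scores sum the keyed contributions of the items
assigned to each of four factors: cognitive (F1, 10 items), manifest
depressed mood (F2, 6 items), somatic 1 (F3, 3 items) and diurnal
variation / somatic 2 (F4, the single "worse in the morning" item).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REVERSE_KEYED_ITEMS",
    "SEVERITY_LEVELS",
    "SdsResponse",
    "SdsResult",
    "FactorStructure",
    "FactorScores",
    "score_sds",
    "classify_depression",
    "factor_scores",
    "keyed_contributions",
    "score_sds_frame",
    "qc_duration_filter",
    "qc_contradiction_filter",
    "qc_breakfast_filter",
]

#: Positively worded SDS items whose keyed contribution is ``5 - score``.
REVERSE_KEYED_ITEMS: frozenset[int] = frozenset({2, 5, 6, 11, 12, 14, 16, 17, 18, 20})

#: Severity labels in increasing order.
SEVERITY_LEVELS: tuple[str, ...] = ("none", "mild", "moderate", "severe")

#: Default item -> factor assignment (promax pattern-matrix grouping).
DEFAULT_ITEM_TO_FACTOR: dict[int, str] = {
    **{i: "F1" for i in (6, 17, 12, 20, 5, 11, 14, 18, 16, 19)},
    **{i: "F2" for i in (3, 15, 10, 4, 13, 1)},
    **{i: "F3" for i in (8, 7, 9)},
    2: "F4",
}

_FACTOR_NAMES = ("F1", "F2", "F3", "F4")


class ValidationError(ValueError):
    """Raised when questionnaire inputs violate the instrument's ranges."""


@dataclass(frozen=True)
class SdsResponse:
    """One student's 20-item SDS record plus completion time in seconds."""

    student_id: str
    items: tuple[int, ...]
    duration_seconds: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.items) != 20:
            raise ValidationError(
                f"SDS requires exactly 20 items, got {len(self.items)} "
                f"for student {self.student_id!r}"
            )
        for k, v in enumerate(self.items, start=1):
            if v not in (1, 2, 3, 4):
                raise ValidationError(
                    f"SDS item {k} for student {self.student_id!r} is {v!r}; "
                    "scores must be in {1, 2, 3, 4}"
                )


@dataclass(frozen=True)
class SdsResult:
    """Derived SDS scores: raw (20-80), standard (raw x 1.25), severity level."""

    raw_score: int
    standard_score: float
    level: str


@dataclass(frozen=True)
class FactorStructure:
    """Assignment of each SDS item to exactly one of four symptom factors."""

    item_to_factor: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_TO_FACTOR)
    )

    def __post_init__(self) -> None:
        missing = set(range(1, 21)) - set(self.item_to_factor)
        if missing:
            raise ValidationError(f"items unassigned to any factor: {sorted(missing)}")
        bad = set(self.item_to_factor.values()) - set(_FACTOR_NAMES)
        if bad:
            raise ValidationError(f"unknown factor labels: {sorted(bad)}")

    def items_of(self, factor: str) -> list[int]:
        return sorted(i for i, f in self.item_to_factor.items() if f == factor)


@dataclass(frozen=True)
class FactorScores:
    """Per-factor sums of keyed item contributions."""

    f1: int
    f2: int
    f3: int
    f4: int

    @property
    def total(self) -> int:
        return self.f1 + self.f2 + self.f3 + self.f4


def _keyed(item_no: int, score: int, keying: frozenset[int]) -> int:
    return 5 - score if item_no in keying else score


def keyed_contributions(
    items: Iterable[int], keying: frozenset[int] = REVERSE_KEYED_ITEMS
) -> list[int]:
    """Keyed contribution of each item (reverse-keyed items contribute 5 - score)."""
    return [_keyed(i, s, keying) for i, s in enumerate(items, start=1)]


def classify_depression(standard_score: float) -> str:
    """Map a standard score in [25, 100] to a severity level.

    Bands: < 53 none, [53, 63) mild, [63, 73) moderate, >= 73 severe.
    """
    s = float(standard_score)
    if not 25.0 <= s <= 100.0:
        raise ValidationError(f"standard score {s} outside [25, 100]")
    if s < 53.0:
        return "none"
    if s < 63.0:
        return "mild"
    if s < 73.0:
        return "moderate"
    return "severe"


def score_sds(
    response: SdsResponse, keying: frozenset[int] = REVERSE_KEYED_ITEMS
) -> SdsResult:
    """Score one SDS response: raw sum, x1.25 standard score, severity level.

    The standard score is kept as a real number (quarter-point resolution);
    no rounding is applied before classification.
    """
    raw = sum(keyed_contributions(response.items, keying))
    standard = raw * 1.25
    return SdsResult(raw_score=raw, standard_score=standard, level=classify_depression(standard))


def factor_scores(
    response: SdsResponse,
    structure: FactorStructure | None = None,
    keying: frozenset[int] = REVERSE_KEYED_ITEMS,
) -> FactorScores:
    """Sum keyed item contributions within each symptom factor."""
    structure = structure or FactorStructure()
    contrib = keyed_contributions(response.items, keying)
    sums = {f: 0 for f in _FACTOR_NAMES}
    for item_no, c in enumerate(contrib, start=1):
        sums[structure.item_to_factor[item_no]] += c
    return FactorScores(f1=sums["F1"], f2=sums["F2"], f3=sums["F3"], f4=sums["F4"])


def score_sds_frame(
    sds: pd.DataFrame,
    keying: frozenset[int] = REVERSE_KEYED_ITEMS,
    structure: FactorStructure | None = None,
) -> pd.DataFrame:
    """Vectorised batch scoring of an SDS table.

    Parameters
    ----------
    sds
        One row per student with columns ``student_id``, ``q1``..``q20`` and
        optionally ``duration_seconds``.

    Returns
    -------
    DataFrame indexed like the input with columns ``student_id``, ``raw``,
    ``standard``, ``level``, ``f1``..``f4``.
    """
    structure = structure or FactorStructure()
    cols = [f"q{i}" for i in range(1, 21)]
    missing = [c for c in cols if c not in sds.columns]
    if missing:
        raise ValidationError(f"SDS table missing columns: {missing}")
    items = sds[cols].to_numpy()
    if items.shape[0] and (items.min() < 1 or items.max() > 4):
        bad = np.argwhere((items < 1) | (items > 4))[0]
        raise ValidationError(
            f"SDS item q{bad[1] + 1} out of range in row {bad[0]}: "
            f"{items[bad[0], bad[1]]!r} not in {{1..4}}"
        )
    rev = np.array([i in keying for i in range(1, 21)])
    contrib = np.where(rev, 5 - items, items)
    out = pd.DataFrame({"student_id": sds["student_id"].to_numpy()}, index=sds.index)
    out["raw"] = contrib.sum(axis=1).astype(int)
    out["standard"] = out["raw"] * 1.25
    out["level"] = pd.cut(
        out["standard"],
        bins=[25.0 - 1e-9, 53.0, 63.0, 73.0, 100.0 + 1e-9],
        labels=SEVERITY_LEVELS,
        right=False,
    ).astype(str)
    for fname in _FACTOR_NAMES:
        idx = [i - 1 for i in structure.items_of(fname)]
        out[fname.lower()] = contrib[:, idx].sum(axis=1).astype(int)
    return out


# ---------------------------------------------------------------------------
# Quality-control screens
# ---------------------------------------------------------------------------

def qc_duration_filter(durations: Mapping[str, float]) -> set[str]:
    """Retain respondents whose completion time is not in the fastest 5%.

    The cutoff is the empirical 5th percentile of all durations computed with
    the linear-interpolation quantile; respondents strictly below it are
    dropped.  A singleton (or any fully tied distribution) is fully retained.
    """
    if not durations:
        raise ValidationError("no respondents supplied")
    vals = np.asarray(list(durations.values()), dtype=float)
    if (vals <= 0).any() or not np.isfinite(vals).all():
        raise ValidationError("durations must be positive finite seconds")
    cutoff = np.percentile(vals, 5.0)  # linear interpolation (numpy default)
    return {sid for sid, d in durations.items() if d >= cutoff}


def qc_contradiction_filter(
    sds_levels: Mapping[str, str],
    bdi_totals: Mapping[str, float],
    bdi_no_depression_cutoff: float = 9.0,
) -> set[str]:
    """Drop respondents whose SDS says moderate/severe but BDI says no depression.

    ``bdi_no_depression_cutoff`` defaults to the classic BDI convention of a
    total <= 9 indicating no depression.
    """
    unmatched = set(sds_levels) - set(bdi_totals)
    if unmatched:
        raise ValidationError(f"no BDI record for ids: {sorted(unmatched)[:5]}")
    retained = set()
    for sid, level in sds_levels.items():
        contradictory = level in ("moderate", "severe") and bdi_totals[sid] <= bdi_no_depression_cutoff
        if not contradictory:
            retained.add(sid)
    return retained


def qc_breakfast_filter(events: pd.DataFrame, meal_windows) -> set[str]:
    """Retain students with at least one canteen swipe inside the breakfast window.

    Students who never swipe at breakfast over the whole observation period
    are treated as off-campus residents and dropped.  ``meal_windows`` is a
    :class:`campusdep.features.MealWindows`.
    """
    if events.empty:
        return set()
    canteen = events[events["venue"] == "canteen"]
    if canteen.empty:
        return set()
    ts = pd.to_datetime(canteen["timestamp"])
    hours = ts.dt.hour + ts.dt.minute / 60 + ts.dt.second / 3600
    lo, hi = meal_windows.breakfast_hours
    in_window = (hours >= lo) & (hours < hi)
    return set(canteen.loc[in_window, "student_id"].unique())
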