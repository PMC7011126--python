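"""Replicated simulation experiments that validate the analysis pipeline.

Three designed experiments, each run over many seeded synthetic cohorts:

* ``null_calibration`` — with every behavioral effect switched off, the
  per-feature Mann-Whitney test between the SDS-classified groups should
  reject at the nominal rate (type-I error calibration);
* ``planted_effect_signs`` — with the default behavioral contrasts planted,
  the depressed group should show later mean breakfast, more late-evening
  dormitory returns and a lower TOP_1 social frequency (direction check);
* ``factor_recovery`` — SDS item data drawn from the planted 4-factor model
  should yield four Kaiser-retained components whose promax pattern
  reassigns items to their planted groups (Tucker congruence / agreement).

Each experiment derives per-replicate seeds from one master seed via
``numpy.random.SeedSequence`` so results are reproducible and replicates
independent.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import features as feat
from . import questionnaire as q
from . import stats as st
from .synthetic import (
    CohortConfig,
    SEVERITY_MIX,
    default_loading_matrix,
    generate_cohort,
    generate_sds_items,
    zero_effect_sizes,
)

__all__ = [
    "short_config",
    "null_calibration",
    "planted_effect_signs",
    "factor_recovery",
    "tucker_congruence",
    "CALIBRATION_FEATURES",
]

#: Representative features spanning the meal, routine and social categories.
CALIBRATION_FEATURES = (
    "Number of breakfasts",
    "Breakfast Time",
    "Number of lunches",
    "22-23 R",
    "TOP_1",
)


def short_config(
    n_students: int = 400,
    weeks: int = 4,
    seed: int = 0,
    effect_sizes: dict | None = None,
) -> CohortConfig:
    """A compact cohort configuration for replicated experiments.

    Shrinks the observation window to ``weeks`` weeks (the social window
    spans the whole of it) while keeping every behavioral rate at its
    default, so replicate loops stay cheap.
    """
    start = dt.date(2017, 9, 11)
    end = start + dt.timedelta(days=7 * weeks - 1)
    kwargs = dict(
        n_students=n_students,
        semester_start=start,
        semester_end=end,
        social_start=start,
        festival_dates=frozenset({start + dt.timedelta(days=20)}),
        seed=seed,
    )
    if effect_sizes is not None:
        kwargs["effect_sizes"] = effect_sizes
    return CohortConfig(**kwargs)


def _features_and_groups(config: CohortConfig, columns) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a cohort, extract features, split by the scored SDS label."""
    cohort = generate_cohort(config)
    table = feat.build_feature_table(
        cohort.card_events, cohort.roster, cohort.calendar, T=250.0, k=5
    )
    scored = q.score_sds_frame(cohort.sds).set_index("student_id").reindex(table.index)
    depressed = (scored["level"] != "none").to_numpy()
    return table[list(columns)], depressed


def null_calibration(
    n_reps: int = 500,
    n_students: int = 400,
    weeks: int = 4,
    seed: int = 0,
    columns=CALIBRATION_FEATURES,
) -> pd.DataFrame:
    """P-values of per-feature group tests under the behavioral null.

    Returns an (n_reps, len(columns)) frame of two-tailed Mann-Whitney
    p-values; each row is one synthetic cohort with all effect sizes
    switched off, groups defined by the scored SDS.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rows = []
    for s in seeds:
        config = short_config(
            n_students=n_students, weeks=weeks, seed=int(s),
            effect_sizes=zero_effect_sizes(),
        )
        table, depressed = _features_and_groups(config, columns)
        row = {}
        for c in columns:
            v = table[c].to_numpy(dtype=float)
            ok = np.isfinite(v)
            row[c] = st.mann_whitney(v[ok & ~depressed], v[ok & depressed]).p_two_tailed
        rows.append(row)
    return pd.DataFrame(rows)


def planted_effect_signs(
    n_reps: int = 100,
    n_students: int = 400,
    weeks: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Direction checks per replicate under the default planted contrasts.

    Columns: ``later_breakfast`` (depressed mean breakfast time higher),
    ``higher_evening_returns`` (depressed mean "22-23 R" higher) and
    ``lower_top1`` (depressed mean TOP_1 lower), one boolean row per seed.
    """
    cols = ("Breakfast Time", "22-23 R", "TOP_1")
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rows = []
    for s in seeds:
        config = short_config(n_students=n_students, weeks=weeks, seed=int(s))
        table, depressed = _features_and_groups(config, cols)
        means = {}
        for c in cols:
            v = table[c].to_numpy(dtype=float)
            ok = np.isfinite(v)
            means[c] = (np.nanmean(v[ok & ~depressed]), np.nanmean(v[ok & depressed]))
        rows.append(
            {
                "later_breakfast": means["Breakfast Time"][1] > means["Breakfast Time"][0],
                "higher_evening_returns": means["22-23 R"][1] > means["22-23 R"][0],
                "lower_top1": means["TOP_1"][1] < means["TOP_1"][0],
            }
        )
    return pd.DataFrame(rows)


def tucker_congruence(pattern: np.ndarray, target: np.ndarray) -> float:
    """Mean Tucker congruence after optimally matching factor columns.

    Columns of ``pattern`` are permuted (by solving the assignment problem
    on absolute congruences) to best match ``target``; signs are ignored,
    as rotation sign is arbitrary.
    """
    A = np.asarray(pattern, float)
    B = np.asarray(target, float)
    k = B.shape[1]
    phi = np.zeros((A.shape[1], k))
    for i in range(A.shape[1]):
        for j in range(k):
            na = np.sqrt((A[:, i] ** 2).sum()) * np.sqrt((B[:, j] ** 2).sum())
            phi[i, j] = abs((A[:, i] * B[:, j]).sum()) / na if na > 0 else 0.0
    ri, ci = linear_sum_assignment(-phi)
    return float(phi[ri, ci].mean())


def factor_recovery(
    n_reps: int = 50,
    n_students: int = 500,
    seed: int = 0,
    loadings: np.ndarray | None = None,
    prevalence: float = 0.2532,
) -> pd.DataFrame:
    """Recovery of the planted SDS factor structure over seeded replicates.

    For each replicate: draw latent severities and item data from the
    planted model, run principal-component factoring with promax rotation
    under the Kaiser rule, and record the number of retained factors, the
    fraction of items whose max-|loading| factor matches the planted
    grouping, and the mean Tucker congruence to the planted loadings.
    """
    L = default_loading_matrix() if loadings is None else np.asarray(loadings, float)
    planted_assignment = np.abs(L).argmax(axis=1)
    probs = np.array([1 - prevalence, *(prevalence * np.asarray(SEVERITY_MIX) / sum(SEVERITY_MIX))])
    rows = []
    for child in np.random.SeedSequence(seed).spawn(n_reps):
        rng = np.random.default_rng(child)
        status = rng.choice(4, size=n_students, p=probs / probs.sum())
        items = generate_sds_items(status, L, rng)
        fa = st.pc_factor_promax(items, retain=None)
        k = fa.n_retained
        if k == 4:
            # align recovered factor columns with the planted ones
            phi = np.zeros((4, 4))
            for i in range(4):
                for j in range(4):
                    a, b = fa.pattern_matrix[:, i], L[:, j]
                    phi[i, j] = abs((a * b).sum()) / (
                        np.linalg.norm(a) * np.linalg.norm(b)
                    )
            ri, ci = linear_sum_assignment(-phi)
            perm = np.empty(4, dtype=int)
            perm[ci] = ri
            recovered = fa.pattern_matrix[:, perm]
            agreement = float(
                (np.abs(recovered).argmax(axis=1) == planted_assignment).mean()
            )
            congruence = tucker_congruence(fa.pattern_matrix, L)
        else:
            agreement = np.nan
            congruence = np.nan
        rows.append(
            {"n_retained": k, "assignment_agreement": agreement, "congruence": congruence}
        )
    return pd.DataFrame(rows)
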