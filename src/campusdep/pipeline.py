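"""End-to-end analysis: from raw cohort tables to the result bundle.

The surface follows the fitted-model idiom: build a
:class:`CampusDepressionModel` from the cohort inputs (event log, roster,
SDS/BDI tables, calendar), call :meth:`~CampusDepressionModel.fit`, and read
the returned :class:`CampusDepressionResults`, which carries

* the cohort description and prevalence summary,
* the gender x severity contingency analysis (chi-square, adjusted
  standardized residuals, odds ratios),
* the per-feature Mann-Whitney group comparison (depressed = any severity),
* the SDS factor analysis (principal-component factoring, promax rotation,
  KMO / Bartlett diagnostics), and
* Spearman/Pearson correlation grids between factor scores and the
  behavioral features (academic features restricted to first-year students).

``run_analysis`` is a thin functional wrapper that reads a cohort directory,
fits the model and writes every table to CSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import questionnaire as q
from . import stats as st

__all__ = [
    "AnalysisConfig",
    "CampusDepressionModel",
    "CampusDepressionResults",
    "SdsFactorModel",
    "run_analysis",
    "summarize_prevalence",
    "grades_long_from_roster",
]

#: SDS item labels in instrument order (1..20).
SDS_ITEM_LABELS = (
    "Depressed affect",
    "Worse in the morning",
    "Crying spells",
    "Sleep disturbance",
    "Decreased appetite",
    "Decreased libido",
    "Weight loss",
    "Constipation",
    "Tachycardia",
    "Fatigue",
    "Confusion",
    "Psychomotor retardation",
    "Psychomotor agitation",
    "Hopelessness",
    "Irritability",
    "Indecisiveness",
    "Personal devaluation",
    "Emptiness",
    "Suicidal ideation",
    "Dissatisfaction",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the full analysis."""

    keying: frozenset = q.REVERSE_KEYED_ITEMS
    bdi_no_depression_cutoff: float = 9.0
    social_window_seconds: float = 250.0
    top_k: int = 5
    meal_windows: feat.MealWindows = field(default_factory=feat.MealWindows)
    first_year_only_academic: bool = True
    promax_kappa: float = 4.0
    min_group_size: int = 2


def grades_long_from_roster(roster: pd.DataFrame) -> pd.DataFrame:
    """Expand per-level course counts (``n_excellent``..``n_fail``) to long form."""
    rows = {"student_id": [], "level": []}
    for lev in feat.GRADE_LEVELS:
        col = f"n_{lev}"
        if col not in roster.columns:
            continue
        counts = roster[col].to_numpy()
        rows["student_id"].extend(np.repeat(roster["student_id"].to_numpy(), counts))
        rows["level"].extend([lev] * int(counts.sum()))
    return pd.DataFrame(rows)


def summarize_prevalence(levels, standard_scores=None, gender=None) -> dict:
    """Overall and per-severity depression percentages (2 d.p.).

    Optionally adds per-gender mean SDS standard scores when
    ``standard_scores`` and ``gender`` are given (aligned sequences).
    """
    levels = pd.Series(list(levels))
    n = len(levels)
    if n == 0:
        raise ValueError("empty cohort")
    out = {
        "n": n,
        "depression_pct": round(float((levels != "none").mean() * 100), 2),
    }
    for lev in ("mild", "moderate", "severe"):
        out[f"{lev}_pct"] = round(float((levels == lev).mean() * 100), 2)
    if standard_scores is not None and gender is not None:
        s = pd.Series(list(standard_scores), dtype=float)
        g = pd.Series(list(gender))
        out["mean_sds_by_gender"] = {
            k: round(float(v), 2) for k, v in s.groupby(g).mean().items()
        }
    return out


class SdsFactorModel:
    """Factor structure of the 20 SDS items, statsmodels-style.

    Parameters
    ----------
    contributions
        (n, 20) matrix of keyed item contributions (1..4 after reverse
        keying).
    """

    def __init__(self, contributions, kappa: float = 4.0):
        self.endog = np.asarray(contributions, dtype=float)
        self.kappa = kappa

    @classmethod
    def from_responses(cls, sds: pd.DataFrame, keying=q.REVERSE_KEYED_ITEMS, **kw):
        items = sds[[f"q{i}" for i in range(1, 21)]].to_numpy()
        rev = np.array([i in keying for i in range(1, 21)])
        return cls(np.where(rev, 5 - items, items), **kw)

    def fit(self, retain: int | None = None) -> st.FactorAnalysisResult:
        return st.pc_factor_promax(self.endog, retain=retain, kappa=self.kappa)


class CampusDepressionModel:
    """The full campus-data depression analysis as a fittable model."""

    def __init__(
        self,
        events: pd.DataFrame,
        roster: pd.DataFrame,
        sds: pd.DataFrame,
        bdi: pd.DataFrame,
        calendar: feat.Calendar,
        grades: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.events = events
        self.roster = roster
        self.sds = sds
        self.bdi = bdi
        self.calendar = calendar
        self.grades = grades if grades is not None else grades_long_from_roster(roster)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_directory(cls, directory, config: AnalysisConfig | None = None):
        from .synthetic import read_cohort

        cohort = read_cohort(directory)
        return cls.from_cohort(cohort, config=config)

    @classmethod
    def from_cohort(cls, cohort, config: AnalysisConfig | None = None):
        return cls(
            events=cohort.card_events,
            roster=cohort.roster,
            sds=cohort.sds,
            bdi=cohort.bdi,
            calendar=cohort.calendar,
            config=config,
        )

    # -- quality control ----------------------------------------------------

    def apply_qc(self) -> tuple[set, dict]:
        """Apply the three screens in order; returns (retained ids, log)."""
        cfg = self.config
        scored = q.score_sds_frame(self.sds, keying=cfg.keying)
        ids0 = set(self.sds["student_id"])
        durations = dict(
            zip(self.sds["student_id"], self.sds["duration_seconds"].astype(float))
        )
        keep1 = q.qc_duration_filter(durations)
        levels = dict(zip(scored["student_id"], scored["level"]))
        bdi_tot = dict(
            zip(
                self.bdi["student_id"],
                self.bdi[[f"b{i}" for i in range(1, 22)]].sum(axis=1),
            )
        )
        keep2 = q.qc_contradiction_filter(
            {k: v for k, v in levels.items() if k in keep1},
            bdi_tot,
            bdi_no_depression_cutoff=cfg.bdi_no_depression_cutoff,
        )
        keep3 = q.qc_breakfast_filter(self.events, cfg.meal_windows)
        retained = keep1 & keep2 & keep3 & set(self.roster["student_id"])
        log = {
            "initial": len(ids0),
            "dropped_duration": len(ids0 - keep1),
            "dropped_contradiction": len((ids0 & keep1) - keep2),
            "dropped_no_breakfast": len((ids0 & keep1 & keep2) - keep3),
            "retained": len(retained),
        }
        return retained, log

    # -- fitting -------------------------------------------------------------

    def fit(self) -> "CampusDepressionResults":
        cfg = self.config
        retained, qc_log = self.apply_qc()
        scored = q.score_sds_frame(self.sds, keying=cfg.keying)
        scored = scored[scored["student_id"].isin(retained)].reset_index(drop=True)
        roster = self.roster[self.roster["student_id"].isin(retained)].reset_index(drop=True)
        events = self.events[self.events["student_id"].isin(retained)]
        grades = self.grades[self.grades["student_id"].isin(retained)]

        table = feat.build_feature_table(
            events,
            roster,
            self.calendar,
            grades=grades,
            windows=cfg.meal_windows,
            T=cfg.social_window_seconds,
            k=cfg.top_k,
        )
        scored = scored.set_index("student_id").reindex(table.index)
        depressed = (scored["level"] != "none").to_numpy()
        n_dep = int(depressed.sum())
        n_non = int((~depressed).sum())
        if min(n_dep, n_non) < cfg.min_group_size:
            raise ValueError(
                f"post-QC groups too small for comparison: {n_non} nondepressed, "
                f"{n_dep} depressed"
            )

        group_comparison, dropped = self._group_comparison(table, depressed)
        qc_log["features_dropped_for_missingness"] = dropped

        gender_tables = self._gender_analysis(roster, scored)
        subsidy = self._subsidy_analysis(roster, depressed, table.index)

        factor_model = SdsFactorModel.from_responses(
            self.sds[self.sds["student_id"].isin(retained)],
            keying=cfg.keying,
            kappa=cfg.promax_kappa,
        )
        fa = factor_model.fit()
        factor_pattern = pd.DataFrame(
            fa.pattern_matrix,
            index=pd.Index(SDS_ITEM_LABELS, name="item"),
            columns=[f"F{j + 1}" for j in range(fa.n_retained)],
        )

        grids = self._correlation_grids(table, scored, roster)

        prevalence = summarize_prevalence(
            scored["level"],
            standard_scores=scored["standard"],
            gender=roster.set_index("student_id").reindex(table.index)["gender"],
        )

        return CampusDepressionResults(
            model=self,
            retained_ids=tuple(table.index),
            qc_log=qc_log,
            feature_table=table,
            scores=scored,
            prevalence=prevalence,
            group_comparison=group_comparison,
            severity_by_gender=gender_tables,
            subsidy_chi2=subsidy,
            factor_analysis=fa,
            factor_pattern=factor_pattern,
            correlation_grids=grids,
        )

    # -- pieces --------------------------------------------------------------

    def _group_comparison(self, table: pd.DataFrame, depressed: np.ndarray):
        rows, dropped = [], []
        numeric = table.select_dtypes(include=[np.number])
        for col in numeric.columns:
            v = numeric[col].to_numpy(dtype=float)
            ok = np.isfinite(v)
            x = v[ok & ~depressed]
            y = v[ok & depressed]
            if len(x) < self.config.min_group_size or len(y) < self.config.min_group_size:
                dropped.append(col)
                continue
            r = st.mann_whitney(x, y)
            rows.append(
                {
                    "feature": col,
                    "U": r.U,
                    "U_min": r.U_min,
                    "z": r.z,
                    "p": r.p_two_tailed,
                    "mean_nondepressive": r.group_means[0],
                    "mean_depressive": r.group_means[1],
                    "n_nondepressive": r.n1,
                    "n_depressive": r.n2,
                }
            )
        return pd.DataFrame(rows).set_index("feature"), dropped

    @staticmethod
    def _gender_analysis(roster: pd.DataFrame, scored: pd.DataFrame) -> dict:
        lev = scored["level"].reindex(
            pd.Index(roster["student_id"], name="student_id")
        )
        gender = roster.set_index("student_id")["gender"]
        order = ["none", "mild", "moderate", "severe"]
        counts = (
            pd.crosstab(gender, lev)
            .reindex(index=["F", "M"], columns=order, fill_value=0)
        )
        out: dict = {"counts": counts}
        tab = counts.to_numpy()
        try:
            res = st.chi_square_independence(tab)
        except st.StatsError:
            return out
        out["chi2"], out["df"], out["p"] = res.chi2, res.df, res.p
        out["asr"] = pd.DataFrame(res.asr, index=counts.index, columns=counts.columns)
        f, m = tab[0], tab[1]
        # male vs female odds of (any) depression and of mild depression
        try:
            out["or_depression"] = st.odds_ratio_2x2(
                [[m[1:].sum(), m[0]], [f[1:].sum(), f[0]]]
            )
            out["or_mild"] = st.odds_ratio_2x2(
                [[m[1], m.sum() - m[1]], [f[1], f.sum() - f[1]]]
            )
        except st.StatsError:
            pass
        return out

    @staticmethod
    def _subsidy_analysis(roster: pd.DataFrame, depressed: np.ndarray, ids) -> dict:
        applied = (
            roster.set_index("student_id")
            .reindex(ids)["n_subsidy_applications"]
            .to_numpy()
            > 0
        )
        tab = np.array(
            [
                [(applied & depressed).sum(), (applied & ~depressed).sum()],
                [(~applied & depressed).sum(), (~applied & ~depressed).sum()],
            ]
        )
        out = {"counts": tab}
        out["rate_depressed_pct"] = round(100 * applied[depressed].mean(), 2) if depressed.any() else np.nan
        out["rate_nondepressed_pct"] = (
            round(100 * applied[~depressed].mean(), 2) if (~depressed).any() else np.nan
        )
        try:
            res = st.chi_square_independence(tab)
            out["chi2"], out["df"], out["p"] = res.chi2, res.df, res.p
        except st.StatsError:
            pass
        return out

    def _correlation_grids(self, table, scored, roster) -> dict:
        score_cols = {"F1": "f1", "F2": "f2", "F3": "f3", "F4": "f4", "SDS": "raw"}

        def grid(feature_cols, frame, method):
            fn = st.spearman if method == "spearman" else st.pearson
            rows_r, rows_p = [], []
            for sname, scol in score_cols.items():
                s = scored.loc[frame.index, scol].to_numpy(dtype=float)
                r_row, p_row = {}, {}
                for c in feature_cols:
                    r, p = fn(s, frame[c].to_numpy(dtype=float))
                    r_row[c], p_row[c] = r, p
                rows_r.append(pd.Series(r_row, name=sname))
                rows_p.append(pd.Series(p_row, name=sname))
            return pd.DataFrame(rows_r), pd.DataFrame(rows_p)

        routine_cols = [c for c in table.columns if c.split(" ")[-1] in ("R", "O")]
        meal_cols = [
            c
            for c in table.columns
            if c.startswith(("Number of breakfast", "Number of lunche", "Number of dinner"))
            or "Time" in c
            or c.startswith("SD of time")
        ]
        top_cols = [c for c in table.columns if c.startswith("TOP_")]
        acad_cols = [
            c
            for c in table.columns
            if c in ("Excellent rate", "Fail rate")
            or c.startswith("Number of ") and c.split(" ")[-1] in feat.GRADE_LEVELS
        ]
        grids = {}
        grids["daily_routine"] = grid(routine_cols, table, "spearman")
        grids["meal_habits"] = grid(meal_cols, table, "spearman")
        acad_table = table
        if self.config.first_year_only_academic and "grade" in roster.columns:
            first_year = roster.loc[roster["grade"] == 1, "student_id"]
            acad_table = table.loc[table.index.intersection(first_year)]
        grids["academic"] = grid(acad_cols, acad_table, "spearman")
        grids["social"] = grid(top_cols, table, "pearson")
        return grids


@dataclass
class CampusDepressionResults:
    """Everything the fitted analysis produced; see :meth:`summary`."""

    model: CampusDepressionModel
    retained_ids: tuple
    qc_log: dict
    feature_table: pd.DataFrame
    scores: pd.DataFrame
    prevalence: dict
    group_comparison: pd.DataFrame
    severity_by_gender: dict
    subsidy_chi2: dict
    factor_analysis: st.FactorAnalysisResult
    factor_pattern: pd.DataFrame
    correlation_grids: dict

    def significant_features(self, alpha: float = 0.05) -> pd.DataFrame:
        gc = self.group_comparison
        return gc[gc["p"] < alpha].sort_values("p")

    def summary(self) -> str:
        p = self.prevalence
        fa = self.factor_analysis
        g = self.severity_by_gender
        lines = [
            "Campus depression analysis",
            "=" * 60,
            f"Cohort after QC: {p['n']} students "
            f"(dropped: {self.qc_log['dropped_duration']} fast completions, "
            f"{self.qc_log['dropped_contradiction']} SDS/BDI contradictions, "
            f"{self.qc_log['dropped_no_breakfast']} never at breakfast)",
            f"Depression prevalence: {p['depression_pct']:.2f}% "
            f"(mild {p['mild_pct']:.2f}%, moderate {p['moderate_pct']:.2f}%, "
            f"severe {p['severe_pct']:.2f}%)",
        ]
        if "chi2" in g:
            lines.append(
                f"Gender x severity: chi2={g['chi2']:.1f}, df={g['df']}, p={g['p']:.3f}"
            )
        if "or_depression" in g:
            o = g["or_depression"]
            lines.append(
                f"OR (male vs female, any depression): {o.or_value:.3f} "
                f"[{o.ci_low:.3f}, {o.ci_high:.3f}]"
            )
        if "chi2" in self.subsidy_chi2:
            s = self.subsidy_chi2
            lines.append(
                f"Subsidy application: {s['rate_nondepressed_pct']}% nondep vs "
                f"{s['rate_depressed_pct']}% dep (chi2={s['chi2']:.1f}, p={s['p']:.3f})"
            )
        lines.append(
            f"Factor analysis: KMO={fa.kmo:.2f}, Bartlett chi2={fa.bartlett_chi2:.1f} "
            f"(df={fa.bartlett_df}, p={fa.bartlett_p:.2g}); "
            f"{fa.n_retained} factors retained "
            f"({', '.join(f'{v:.2f}%' for v in fa.variance_explained_pct)} variance)"
        )
        sig = self.significant_features()
        lines.append(f"Features significant at p<.05 (Mann-Whitney): {len(sig)}")
        for name, row in sig.head(10).iterrows():
            lines.append(
                f"  {name}: U={row['U']:.1f}, z={row['z']:.2f}, p={row['p']:.3f}, "
                f"means {row['mean_nondepressive']:.2f} vs {row['mean_depressive']:.2f}"
            )
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Write all tables; rounding is applied only here (2 d.p. for means
        and test statistics, 3 d.p. for odds ratios and correlations)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        gc = self.group_comparison.copy()
        for c in ("U", "U_min", "z", "mean_nondepressive", "mean_depressive"):
            gc[c] = gc[c].round(2)
        gc["p"] = gc["p"].round(4)
        gc.to_csv(d / "group_comparison.csv")
        g = self.severity_by_gender
        g["counts"].to_csv(d / "severity_by_gender_counts.csv")
        if "asr" in g:
            g["asr"].round(1).to_csv(d / "severity_by_gender_asr.csv")
        self.factor_pattern.round(3).to_csv(d / "factor_pattern.csv")
        for name, (r, p) in self.correlation_grids.items():
            r.round(3).to_csv(d / f"corr_{name}_r.csv")
            p.round(4).to_csv(d / f"corr_{name}_p.csv")
        meta = {
            "prevalence": self.prevalence,
            "qc_log": self.qc_log,
            "gender_chi2": {
                k: (round(float(g[k]), 4) if isinstance(g.get(k), float) else g.get(k))
                for k in ("chi2", "df", "p")
                if k in g
            },
            "odds_ratios": {
                k: {
                    "or": round(g[k].or_value, 3),
                    "ci_low": round(g[k].ci_low, 3),
                    "ci_high": round(g[k].ci_high, 3),
                }
                for k in ("or_depression", "or_mild")
                if k in g
            },
            "subsidy": {
                k: (float(v) if np.isscalar(v) else None)
                for k, v in self.subsidy_chi2.items()
                if k != "counts"
            },
            "factor_analysis": {
                "kmo": round(self.factor_analysis.kmo, 3),
                "bartlett_chi2": round(self.factor_analysis.bartlett_chi2, 1),
                "bartlett_df": self.factor_analysis.bartlett_df,
                "n_retained": self.factor_analysis.n_retained,
                "variance_explained_pct": [
                    round(float(v), 2) for v in self.factor_analysis.variance_explained_pct
                ],
            },
        }
        (d / "prevalence.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        (d / "summary.txt").write_text(self.summary() + "\n")


def run_analysis(input_dir, output_dir=None, config: AnalysisConfig | None = None):
    """Read a cohort directory, fit the full analysis, optionally save tables."""
    results = CampusDepressionModel.from_directory(input_dir, config=config).fit()
    if output_dir is not None:
        results.save(output_dir)
    return results
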