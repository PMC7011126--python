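"""Feature extraction: meals, routine, social matrix, academic, misc."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from campusdep import features as feat
from tests.helpers import brute_force_social, events_from_times, make_events


@pytest.fixture
def calendar():
    return feat.Calendar(
        observation_start=dt.date(2017, 9, 11),
        observation_end=dt.date(2018, 1, 10),
        festival_dates=frozenset({dt.date(2017, 10, 2), dt.date(2017, 10, 3)}),
        social_start=dt.date(2017, 11, 20),
    )


class TestMealAssignment:
    def test_first_swipe_wins(self, calendar):
        ev = make_events(
            [
                ("A", "2017-09-12T07:10:00", "canteen", "n/a", 4.0),
                ("A", "2017-09-12T07:40:00", "canteen", "n/a", 2.0),
            ]
        )
        meals = feat.assign_meals(ev)
        assert len(meals) == 1
        assert meals.iloc[0]["meal"] == "breakfast"
        assert meals.iloc[0]["time_hours"] == pytest.approx(7 + 10 / 60)

    def test_no_swipe_no_record(self):
        ev = make_events([("A", "2017-09-12T07:10:00", "canteen", "n/a", 4.0)])
        meals = feat.assign_meals(ev)
        assert set(meals["meal"]) == {"breakfast"}

    def test_window_end_boundary_excluded(self):
        # breakfast window is [05:00, 10:00): a 10:00:00 swipe is not breakfast
        ev = make_events([("A", "2017-09-12T10:00:00", "canteen", "n/a", 4.0)])
        meals = feat.assign_meals(ev)
        assert "breakfast" not in set(meals["meal"])

    def test_swipe_outside_all_windows_ignored(self):
        ev = make_events([("A", "2017-09-12T15:30:00", "canteen", "n/a", 4.0)])
        assert feat.assign_meals(ev).empty

    def test_non_canteen_ignored(self):
        ev = make_events([("A", "2017-09-12T07:10:00", "dorm_door", "in", 0.0)])
        assert feat.assign_meals(ev).empty


class TestMealFeatures:
    def test_mean_and_sample_sd(self, calendar):
        ev = make_events(
            [
                ("A", "2017-09-12T07:30:00", "canteen", "n/a", 4.0),
                ("A", "2017-09-13T08:30:00", "canteen", "n/a", 4.0),
            ]
        )
        mf = feat.meal_features(feat.assign_meals(ev), calendar)
        assert mf.loc["A", "Breakfast Time"] == pytest.approx(8.0)
        assert mf.loc["A", "SD of time of breakfast"] == pytest.approx(0.7071, abs=1e-4)
        assert mf.loc["A", "Number of breakfasts"] == 2

    def test_single_record_sd_missing(self, calendar):
        ev = make_events([("A", "2017-09-12T12:00:00", "canteen", "n/a", 4.0)])
        mf = feat.meal_features(feat.assign_meals(ev), calendar)
        assert mf.loc["A", "Number of lunches"] == 1
        assert np.isnan(mf.loc["A", "SD of time of lunch"])
        assert np.isnan(mf.loc["A", "Lunch Time"])

    def test_constant_lunch_time(self, calendar):
        rows = [
            ("A", f"2017-09-{d:02d}T11:45:00", "canteen", "n/a", 4.0) for d in (12, 13, 14)
        ]
        mf = feat.meal_features(feat.assign_meals(make_events(rows)), calendar)
        assert mf.loc["A", "Lunch Time"] == pytest.approx(11.75)
        assert mf.loc["A", "SD of time of lunch"] == pytest.approx(0.0)

    def test_festival_nonfestival_split_conserves_total(self, calendar):
        rows = [
            ("A", "2017-10-02T07:30:00", "canteen", "n/a", 4.0),  # festival
            ("A", "2017-10-04T07:30:00", "canteen", "n/a", 4.0),  # nonfestival
            ("A", "2017-10-05T07:30:00", "canteen", "n/a", 4.0),
        ]
        meals = feat.assign_meals(make_events(rows))
        mf = feat.meal_features(meals, calendar)
        total = (
            mf.loc["A", "Number of breakfasts"]
            + mf.loc["A", "Number of breakfasts during festival"]
        )
        assert total == len(meals)
        assert mf.loc["A", "Number of breakfasts during festival"] == 1


class TestRoutineFeatures:
    def test_single_return_event(self, calendar):
        ev = make_events([("A", "2017-09-12T08:15:00", "dorm_door", "in", 0.0)])
        rf = feat.routine_features(ev, calendar)
        assert rf.loc["A", "8-9 R"] == 1
        assert rf.drop(columns=["8-9 R"]).loc["A"].sum() == 0

    def test_festival_late_exit(self, calendar):
        ev = make_events([("A", "2017-10-02T23:59:00", "dorm_door", "out", 0.0)])
        rf = feat.routine_features(ev, calendar)
        assert rf.loc["A", "23-24 O festival"] == 1

    def test_repeated_bin_counts(self, calendar):
        rows = [
            ("A", f"2017-09-{d:02d}T22:{m:02d}:00", "dorm_door", "in", 0.0)
            for d, m in ((12, 0), (13, 30), (14, 59))
        ]
        rf = feat.routine_features(make_events(rows), calendar)
        assert rf.loc["A", "22-23 R"] == 3

    def test_hour_boundary_belongs_to_later_bin(self, calendar):
        ev = make_events([("A", "2017-09-12T09:00:00", "dorm_door", "out", 0.0)])
        rf = feat.routine_features(ev, calendar)
        assert rf.loc["A", "9-10 O"] == 1
        assert rf.loc["A", "8-9 O"] == 0

    def test_conservation_over_bins(self, calendar):
        rng = np.random.default_rng(0)
        rows = []
        for k in range(300):
            day = dt.date(2017, 9, 11) + dt.timedelta(days=int(rng.integers(0, 100)))
            ts = f"{day}T{rng.integers(0, 24):02d}:{rng.integers(0, 60):02d}:00"
            rows.append(
                (f"S{rng.integers(0, 5)}", ts, "dorm_door",
                 "in" if rng.random() < 0.5 else "out", 0.0)
            )
        ev = make_events(rows)
        rf = feat.routine_features(ev, calendar)
        per_student = ev.groupby("student_id").size()
        np.testing.assert_array_equal(rf.sum(axis=1).to_numpy(),
                                      per_student.reindex(rf.index).to_numpy())

    def test_missing_direction_rejected(self, calendar):
        ev = make_events([("A", "2017-09-12T08:15:00", "dorm_door", "n/a", 0.0)])
        with pytest.raises(feat.FeatureError):
            feat.routine_features(ev, calendar)


class TestSocialMatrix:
    def test_single_pair_within_window(self):
        sm = feat.social_frequency_matrix(events_from_times({"i": [0], "j": [100]}))
        assert sm.R[0, 1] == sm.R[1, 0] == 1

    def test_two_pairs_example(self):
        sm = feat.social_frequency_matrix(
            events_from_times({"i": [0, 1000], "j": [100, 1200]})
        )
        assert sm.R[0, 1] == 2  # 0<->100 and 1000<->1200 only

    def test_disjoint_times_zero(self):
        sm = feat.social_frequency_matrix(
            events_from_times({"i": [0, 600], "j": [5000]})
        )
        assert sm.R[0, 1] == 0

    def test_boundary_closed(self):
        sm = feat.social_frequency_matrix(events_from_times({"i": [0], "j": [250]}))
        assert sm.R[0, 1] == 1
        sm = feat.social_frequency_matrix(events_from_times({"i": [0], "j": [251]}))
        assert sm.R[0, 1] == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(2, 12))
            times = {
                f"S{i:02d}": rng.uniform(0, 20000, rng.integers(0, 40)).round(0)
                for i in range(n)
            }
            ids, ref = brute_force_social(times, 250.0)
            sm = feat.social_frequency_matrix(events_from_times(times), ids=ids)
            np.testing.assert_array_equal(sm.R, ref)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        times = {f"S{i}": rng.uniform(0, 5000, 20) for i in range(4)}
        shifted = {k: v + 7200 for k, v in times.items()}
        a = feat.social_frequency_matrix(events_from_times(times))
        b = feat.social_frequency_matrix(events_from_times(shifted))
        np.testing.assert_array_equal(a.R, b.R)

    def test_symmetry_and_zero_diagonal_summaries(self):
        rng = np.random.default_rng(6)
        times = {f"S{i}": rng.uniform(0, 3000, 15) for i in range(5)}
        sm = feat.social_frequency_matrix(events_from_times(times))
        np.testing.assert_array_equal(sm.R, sm.R.T)

    def test_social_window_restriction(self):
        rows = [
            ("A", "2017-10-01T12:00:00", "canteen", "n/a", 5.0),  # before window
            ("B", "2017-10-01T12:01:00", "canteen", "n/a", 5.0),
            ("A", "2017-12-01T12:00:00", "canteen", "n/a", 5.0),  # inside window
            ("B", "2017-12-01T12:01:00", "canteen", "n/a", 5.0),
        ]
        sm = feat.social_frequency_matrix(
            make_events(rows), start=dt.date(2017, 11, 20), end=dt.date(2018, 1, 10)
        )
        assert sm.R[0, 1] == 1

    def test_invalid_T_rejected(self):
        with pytest.raises(feat.FeatureError):
            feat.social_frequency_matrix(events_from_times({"i": [0], "j": [1]}), T=0)


class TestTopK:
    @staticmethod
    def matrix(row):
        n = len(row) + 1
        R = np.zeros((n, n), dtype=int)
        R[0, 1:] = row
        R[1:, 0] = row
        return feat.SocialMatrix(ids=tuple(f"S{i}" for i in range(n)), R=R, window_T=250.0)

    def test_sorted_padded(self):
        top = feat.top_k_social(self.matrix([7, 3, 9, 1]))
        assert top.loc["S0"].tolist() == [9, 7, 3, 1, 0]

    def test_all_zero_row(self):
        top = feat.top_k_social(self.matrix([0, 0, 0]))
        assert top.loc["S0"].tolist() == [0, 0, 0, 0, 0]

    def test_ties_preserved(self):
        top = feat.top_k_social(self.matrix([5, 5, 2]))
        assert top.loc["S0"].tolist() == [5, 5, 2, 0, 0]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        n = 8
        R = rng.integers(0, 20, (n, n))
        R = R + R.T
        np.fill_diagonal(R, 0)
        ids = tuple(f"S{i}" for i in range(n))
        base = feat.top_k_social(feat.SocialMatrix(ids=ids, R=R, window_T=250.0))
        perm = rng.permutation(n)
        permuted = feat.top_k_social(
            feat.SocialMatrix(
                ids=tuple(ids[i] for i in perm), R=R[np.ix_(perm, perm)], window_T=250.0
            )
        )
        pd.testing.assert_frame_equal(base.sort_index(), permuted.sort_index())

    def test_invalid_k(self):
        with pytest.raises(feat.FeatureError):
            feat.top_k_social(self.matrix([1]), k=0)


class TestAcademicFeatures:
    def test_rates(self):
        g = pd.DataFrame(
            {"student_id": ["A"] * 4, "level": ["excellent", "fail", "pass", "pass"]}
        )
        af = feat.academic_features(g)
        assert af.loc["A", "Excellent rate"] == pytest.approx(0.25)
        assert af.loc["A", "Fail rate"] == pytest.approx(0.25)

    def test_all_excellent_zero_fail_rate(self):
        g = pd.DataFrame({"student_id": ["A"] * 3, "level": ["excellent"] * 3})
        assert feat.academic_features(g).loc["A", "Fail rate"] == 0.0

    def test_zero_courses_rates_missing(self):
        g = pd.DataFrame({"student_id": ["A"], "level": ["pass"]})
        af = feat.academic_features(g, ids=["A", "B"])
        assert np.isnan(af.loc["B", "Excellent rate"])
        assert af.loc["B", "Number of pass"] == 0

    def test_unknown_level_rejected(self):
        g = pd.DataFrame({"student_id": ["A"], "level": ["stellar"]})
        with pytest.raises(feat.FeatureError):
            feat.academic_features(g)


class TestMiscFeatures:
    @staticmethod
    def roster(ids):
        return pd.DataFrame(
            {
                "student_id": ids,
                "n_subsidy_applications": [2] * len(ids),
                "subsidy_this_year": [1] * len(ids),
                "total_books_borrowed": [7] * len(ids),
                "semester_books_borrowed": [3] * len(ids),
            }
        )

    def test_counts_and_passthrough(self):
        ev = make_events(
            [
                ("A", "2017-09-12T10:00:00", "library", "n/a", 0.0),
                ("A", "2017-09-13T10:00:00", "library", "n/a", 0.0),
                ("A", "2017-09-13T20:00:00", "water", "n/a", 1.5),
            ]
        )
        mf = feat.misc_features(ev, self.roster(["A", "B"]))
        assert mf.loc["A", "Number of library visits"] == 2
        assert mf.loc["B", "Number of library visits"] == 0
        assert mf.loc["A", "Water intake"] == 1
        assert mf.loc["A", "Number of subsidy applications"] == 2
        assert mf.loc["A", "Total books borrowed"] == 7

    def test_weekly_mean(self):
        rows = [
            ("A", f"2017-09-{d:02d}T12:00:00", "canteen", "n/a", amt)
            # Mondays of four ISO weeks
            for d, amt in ((11, 10.0), (18, 20.0), (25, 30.0))
        ] + [("A", "2017-10-02T12:00:00", "canteen", "n/a", 40.0)]
        mf = feat.misc_features(make_events(rows), self.roster(["A"]))
        assert mf.loc["A", "Weekly consumption mean"] == pytest.approx(25.0)

    def test_negative_amount_rejected(self):
        ev = make_events([("A", "2017-09-12T12:00:00", "canteen", "n/a", -5.0)])
        with pytest.raises(feat.FeatureError):
            feat.misc_features(ev, self.roster(["A"]))


class TestFullTable:
    def test_builds_with_all_blocks(self, calendar):
        rng = np.random.default_rng(4)
        rows = []
        for sid in ("A", "B", "C"):
            for d in range(20):
                day = dt.date(2017, 11, 21) + dt.timedelta(days=d)
                rows.append((sid, f"{day}T07:{rng.integers(0, 60):02d}:00", "canteen", "n/a", 5.0))
                rows.append((sid, f"{day}T22:15:00", "dorm_door", "in", 0.0))
        roster = TestMiscFeatures.roster(["A", "B", "C"])
        grades = pd.DataFrame(
            {"student_id": ["A", "A", "B", "C"], "level": ["excellent", "fail", "pass", "good"]}
        )
        table = feat.build_feature_table(make_events(rows), roster, calendar, grades=grades)
        assert table.shape[0] == 3
        for col in ("Number of breakfasts", "22-23 R", "TOP_1", "Fail rate",
                    "Number of library visits"):
            assert col in table.columns
        assert (table["22-23 R"] == 20).all()
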