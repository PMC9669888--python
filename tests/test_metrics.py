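import datetime as dt

import numpy as np
import pandas as pd
import pytest

from inhalytics import (
    StudyConfig,
    assign_day_index,
    categorize_early_adherence,
    day_proportion,
    detect_high_use,
    moving_average,
    pooled_adherence,
    summarize,
    time_of_day_histogram,
    weekday_profile,
)
from inhalytics.attribution import daily_table
from inhalytics.metrics import adherence_trend

from conftest import make_events
from test_attribution import days_from_totals


class TestRatios:
    def test_pooled_adherence(self):
        assert pooled_adherence(108040, 153820) == 70.2
        assert pooled_adherence(6332, 9520) == 66.5
        assert pooled_adherence(0, 100) == 0.0

    def test_day_proportion(self):
        assert day_proportion(31812, 56175) == 56.6
        assert day_proportion(9534, 56175) == 17.0
        assert day_proportion(5, 5) == 100.0

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            pooled_adherence(0, 0)
        with pytest.raises(ValueError):
            day_proportion(1, 0)


def with_regimen(days, regimen="1BID", m=2):
    days = days.copy()
    days["regimen"] = regimen
    days["m_prescribed"] = m
    return days


class TestSummarize:
    def test_hand_counted_example(self):
        # one M=2 patient, day totals (2, 0, 1): 3 of 6 doses, 1 full, 1 zero day
        days = with_regimen(days_from_totals([2, 0, 1], m=2))
        s = summarize(days, window=(1, 3))
        assert s.pooled_adherence_pct == 50.0
        assert (s.fully_adherent_days, s.zero_dose_days, s.day_denominator) == (1, 1, 3)
        assert s.maintenance_prescribed_sum == 2 * s.day_denominator

    def test_all_full_days(self):
        days = with_regimen(days_from_totals([2, 2, 2], m=2))
        s = summarize(days, window=(1, 3))
        assert s.pooled_adherence_pct == 100.0
        assert s.zero_dose_days == 0

    def test_group_additivity(self):
        one = with_regimen(days_from_totals([2, 0, 1], m=2))
        two = with_regimen(days_from_totals([2, 0, 1], m=2, patient="B"))
        s1 = summarize(one, window=(1, 3))
        s2 = summarize(pd.concat([one, two], ignore_index=True), window=(1, 3))
        assert s2.maintenance_taken_sum == 2 * s1.maintenance_taken_sum
        assert s2.day_denominator == 2 * s1.day_denominator
        assert s2.pooled_adherence_pct == s1.pooled_adherence_pct

    def test_incomplete_window_errors(self):
        days = with_regimen(days_from_totals([2, 0], m=2))
        with pytest.raises(ValueError, match="incomplete"):
            summarize(days, window=(1, 3))

    def test_merged_group_pooled_between_subgroups(self):
        a = with_regimen(days_from_totals([2, 2, 2], m=2))
        b = with_regimen(days_from_totals([0, 0, 2], m=2, patient="B"))
        merged = summarize(pd.concat([a, b], ignore_index=True), window=(1, 3))
        lo = summarize(b, window=(1, 3)).pooled_adherence_pct
        hi = summarize(a, window=(1, 3)).pooled_adherence_pct
        assert lo <= merged.pooled_adherence_pct <= hi


class TestMovingAverage:
    def test_forced_arithmetic(self):
        out = moving_average([0, 1, 1], 3)
        assert out[1] == pytest.approx(2 / 3)
        assert out[0] == 0 and out[2] == 1  # edge windows shrink to width 1

    def test_constant_series_unchanged(self):
        assert np.allclose(moving_average([5.0] * 10, 5), 5.0)

    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_brute_force(self, window):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        out = moving_average(x, window)
        half = window // 2
        for i in range(len(x)):
            k = min(half, i, len(x) - 1 - i)
            assert out[i] == pytest.approx(x[i - k : i + k + 1].mean())

    def test_output_length_preserved(self):
        assert len(moving_average([1.0], 3)) == 1


class TestWeekdayProfile:
    def test_all_full_days_are_100(self):
        days = with_regimen(days_from_totals([2] * 14, m=2))
        prof = weekday_profile(days, window=(1, 14))
        assert np.allclose(prof["1BID"].to_numpy(), 100.0)

    def test_single_weekday_adherence(self):
        # 2018-01-01 is a Monday; dose only on Mondays over 2 weeks
        totals = [2 if i % 7 == 0 else 0 for i in range(14)]
        days = with_regimen(days_from_totals(totals, m=2))
        prof = weekday_profile(days, window=(1, 14))
        assert prof.loc["Mon", "1BID"] == 100.0
        assert prof.loc["Tue", "1BID"] == 0.0

    def test_simulated_weekend_dip(self, sim_cohort):
        params, cohort = sim_cohort
        config = params.study_config()
        from inhalytics import apply_inclusion

        inc = apply_inclusion(cohort.events, cohort.registry, config)
        days = daily_table(inc.events, inc.patients, config, window_end_day=90)
        prof = weekday_profile(days, window=(1, 90))
        weekend = prof.loc[["Sat", "Sun"]].mean().mean()
        midweek = prof.loc[["Tue", "Wed", "Thu"]].mean().mean()
        assert weekend < midweek


class TestTimeOfDayHistogram:
    def test_single_bin(self):
        events = assign_day_index(make_events([("A", "2018-01-01T08:15")] * 10))
        hist = time_of_day_histogram(events, window=(1, 90))
        assert hist["count"].sum() == 10
        assert hist.loc[hist["bin_start"] == "08:00", "count"].iloc[0] == 10

    def test_empty_window_all_zero(self):
        events = assign_day_index(make_events([("A", "2018-01-01T08:15")]))
        hist = time_of_day_histogram(events, window=(50, 90))
        assert hist["count"].sum() == 0

    def test_simulated_bimodal_morning_evening(self, sim_cohort):
        """Under the default dose-time mixture, most inhalations fall in the
        06:00-10:00 and 18:00-22:00 windows."""
        params, cohort = sim_cohort
        annotated = pd.concat(
            [assign_day_index(g) for _, g in cohort.events.groupby("patient_id")],
            ignore_index=True,
        )
        hist = time_of_day_histogram(annotated, window=(1, 90))
        in_windows = hist[
            ((hist["minute_start"] >= 360) & (hist["minute_start"] < 600))
            | ((hist["minute_start"] >= 1080) & (hist["minute_start"] < 1320))
        ]["count"].sum()
        assert in_windows / hist["count"].sum() >= 0.6


class TestHighUse:
    def test_threshold_is_strict(self):
        days = with_regimen(pd.concat(
            [days_from_totals([13], m=2), days_from_totals([12], m=2, patient="B")],
            ignore_index=True,
        ))
        report = detect_high_use(days, threshold=12)
        assert report.n_high_use_days == 1
        assert report.n_patients_high_use == 1

    def test_mean_median_range_per_affected_patient(self):
        # 3 affected patients with 1, 2 and 4 high-use days among 5 patients
        frames = []
        for pid, n_high in [("A", 1), ("B", 2), ("C", 4), ("D", 0), ("E", 0)]:
            totals = [13] * n_high + [2] * (10 - n_high)
            frames.append(with_regimen(days_from_totals(totals, m=2, patient=pid)))
        report = detect_high_use(pd.concat(frames, ignore_index=True))
        assert report.n_high_use_days == 7
        assert report.mean_days_per_affected == pytest.approx(7 / 3)
        assert report.median_days_per_affected == 2
        assert report.range_days_per_affected == (1, 4)
        assert report.person_days == 50
        assert report.rate_per_100_person_days == round(100 * 7 / 50, 2)

    def test_regimen_breakdown_conserves_totals(self, sim_cohort):
        params, cohort = sim_cohort
        config = params.study_config()
        from inhalytics import apply_inclusion

        inc = apply_inclusion(cohort.events, cohort.registry, config)
        days = daily_table(inc.events, inc.patients, config)
        report = detect_high_use(days, threshold=config.high_use_threshold)
        assert report.by_regimen["n_high_use_days"].sum() == report.n_high_use_days
        assert report.by_regimen["person_days"].sum() == report.person_days


class TestEarlyAdherenceCategory:
    def make_config(self):
        return StudyConfig(cutoff_date=dt.date(2018, 11, 11))

    @pytest.mark.parametrize(
        "taken,expected",
        [
            (20, "low"),     # 20/30 = 66.7%
            (21, "medium"),  # 21/30 = 70.0% -> boundary lands in medium
            (26, "medium"),  # 86.7%
            (27, "high"),    # 90.0% -> boundary lands in high
            (30, "high"),
        ],
    )
    def test_cutoff_boundaries(self, taken, expected):
        totals = [2] * (taken // 2) + ([1] if taken % 2 else [])
        totals += [0] * (15 - len(totals))
        days = with_regimen(days_from_totals(totals, m=2))
        cats = categorize_early_adherence(days, self.make_config())
        assert cats.loc[0, "category"] == expected

    def test_short_follow_up_excluded(self):
        days = with_regimen(days_from_totals([2] * 10, m=2))
        cats = categorize_early_adherence(days, self.make_config())
        assert cats.loc[0, "category"] is None


def test_adherence_trend_smoothing_matches_window(sim_cohort):
    params, cohort = sim_cohort
    config = params.study_config()
    from inhalytics import apply_inclusion

    inc = apply_inclusion(cohort.events, cohort.registry, config)
    days = daily_table(inc.events, inc.patients, config, window_end_day=90)
    trend = adherence_trend(days, window=(1, 90), ma_window=5)
    one = trend[trend["regimen"] == trend["regimen"].iloc[0]]
    assert len(one) == 90
    recompute = moving_average(one["adherence_pct"].to_numpy(), 5)
    assert np.allclose(one["smoothed_pct"].to_numpy(), recompute)
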