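from datetime import date

import numpy as np
import pytest

from thermosow.core_model import ClimateDay, ClimateSeries, ValidationError
from thermosow.site_application import (
    accumulation_period,
    climate_summary,
    detect_rainy_season,
    initial_requirement_date,
    last_requirement_date,
    monthly_precipitation,
    ref_doy,
    score_series,
    sowing_window,
)
from thermosow.synthetic_data import GARIWANG_MONTHLY_PRECIP
from thermosow.ts_model import daily_ts, fit_species_model
from thermosow.synthetic_data import DMT_LEVELS, DTR_LEVELS, gariwang_like_params, simulate_climate

from conftest import make_score_series


def run_series(year, positive_days):
    """365-day ts series: +1 on the given 1-based days, -1 elsewhere."""
    ts = -np.ones(365)
    ts[[d - 1 for d in positive_days]] = 1.0
    return {year: ts}


class TestScoreSeries:
    def test_length_preserved_and_matches_reevaluation(self, small_dataset):
        model = fit_species_model(small_dataset, DMT_LEVELS, DTR_LEVELS)
        climate = simulate_climate(gariwang_like_params(rng_seed=6), 2015, 1)
        scores = score_series(model, climate)
        assert len(scores.frame) == len(climate.days)
        for _, row in scores.frame.sample(20, random_state=0).iterrows():
            assert row["ts"] == pytest.approx(
                daily_ts(model, row["dmt"], row["dtr"])
            )


class TestAccumulationPeriod:
    def test_single_year_run(self):
        scores = make_score_series(run_series(2001, range(100, 201)))
        period = accumulation_period(scores)
        assert (period.start_doy, period.end_doy) == (100, 200)

    def test_two_year_intersection(self):
        scores = make_score_series(
            {**run_series(2001, range(100, 201)), **run_series(2002, range(120, 181))}
        )
        period = accumulation_period(scores)
        assert (period.start_doy, period.end_doy) == (120, 180)

    def test_empty_intersection_rejected(self):
        scores = make_score_series(
            {**run_series(2001, range(50, 100)), **run_series(2002, range(200, 250))}
        )
        with pytest.raises(ValidationError, match="no common favorable"):
            accumulation_period(scores)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_run_scan(self, seed):
        rng = np.random.default_rng(seed)
        ts = rng.choice([-1.0, 1.0], size=365, p=[0.4, 0.6])
        scores = make_score_series({2001: ts})

        best_len, best = 0, None  # brute-force over all (i, j) windows
        for i in range(365):
            for j in range(i, 365):
                if np.all(ts[i : j + 1] > 0) and j - i + 1 > best_len:
                    best_len, best = j - i + 1, (i + 1, j + 1)
        period = accumulation_period(scores)
        assert (period.start_doy, period.end_doy) == best


class TestRequirementDates:
    def test_constant_ts_reaches_on_tenth_day(self):
        scores = make_score_series({2001: np.where(np.arange(365) < 50, 10.0, -1.0)})
        res = initial_requirement_date(scores, 100.0, sowing_doy=1)
        assert res.mean_doy == 10

    def test_zero_requirement_returns_start(self):
        scores = make_score_series(run_series(2001, range(100, 201)))
        res = initial_requirement_date(scores, 0.0, sowing_doy=50)
        assert res.mean_doy == 100  # accumulation start dominates April sowing

    def test_missed_year_excluded_with_warning(self):
        big = np.where(np.arange(365) < 100, 5.0, -1.0)
        small = np.where(np.arange(365) < 100, 0.1, -1.0)
        scores = make_score_series({2001: big, 2002: small})
        res = initial_requirement_date(scores, 100.0, sowing_doy=1)
        assert res.missed_years == [2002]
        assert res.by_year[2002] is None

    @pytest.mark.parametrize("seed", range(3))
    def test_initial_matches_cumsum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ts = rng.uniform(0, 5, size=365)
        scores = make_score_series({2001: ts})
        req = 200.0
        res = initial_requirement_date(scores, req, sowing_doy=1)
        cum = 0.0  # day-by-day scan oracle
        for i, t in enumerate(ts):
            cum += max(0.0, t)
            if cum >= req:
                assert res.mean_doy == i + 1
                break

    def test_last_constant_ts(self):
        ts = np.concatenate([10.0 * np.ones(100), -np.ones(265)])
        scores = make_score_series({2001: ts})
        res = last_requirement_date(scores, 100.0)
        assert res.mean_doy == 91

    def test_last_requirement_equal_to_total_returns_start(self):
        ts = np.concatenate([10.0 * np.ones(100), -np.ones(265)])
        scores = make_score_series({2001: ts})
        res = last_requirement_date(scores, 1000.0)
        assert res.mean_doy == 1

    def test_last_exceeding_total_rejected(self):
        scores = make_score_series(run_series(2001, range(100, 120)))
        with pytest.raises(ValidationError, match="below requirement"):
            last_requirement_date(scores, 1e6)

    @pytest.mark.parametrize("seed", range(3))
    def test_last_matches_reverse_cumsum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ts = np.concatenate([rng.uniform(0, 5, size=250), -np.ones(115)])
        scores = make_score_series({2001: ts})
        req = 150.0
        res = last_requirement_date(scores, req)
        end = 249  # last positive day index (0-based)
        tail = np.cumsum(np.maximum(0, ts[: end + 1])[::-1])[::-1]
        expected = int(np.max(np.nonzero(tail >= req)[0])) + 1
        assert res.mean_doy == expected

    def test_requirement_date_monotone_in_requirement(self):
        rng = np.random.default_rng(7)
        ts = rng.uniform(0, 5, size=365)
        scores = make_score_series({2001: ts})
        i1 = initial_requirement_date(scores, 100.0, 1).mean_doy
        i2 = initial_requirement_date(scores, 300.0, 1).mean_doy
        l1 = last_requirement_date(scores, 100.0).mean_doy
        l2 = last_requirement_date(scores, 300.0).mean_doy
        assert i1 <= i2 and l1 >= l2
        assert i1 <= l1 and i2 <= l2


class TestClimateSummary:
    def test_single_day(self):
        s = ClimateSeries("x", [ClimateDay(date(2015, 1, 1), 5.0, -5.0)])
        cs = climate_summary(s)
        assert (cs.max_tmax, cs.min_tmin, cs.mean_dmt, cs.mean_dtr) == (5.0, -5.0, 0.0, 10.0)

    def test_invariant_to_row_order(self):
        days = [
            ClimateDay(date(2015, 1, 1), 5.0, -5.0),
            ClimateDay(date(2015, 1, 2), 10.0, 2.0),
            ClimateDay(date(2015, 1, 3), -1.0, -9.0),
        ]
        assert climate_summary(ClimateSeries("x", days)) == climate_summary(
            ClimateSeries("x", days[::-1])
        )

    def test_matches_streaming_oracle(self):
        rng = np.random.default_rng(0)
        days, mx, mn = [], -np.inf, np.inf
        dmts, dtrs = [], []
        for i in range(200):
            mid, half = rng.uniform(-10, 25), rng.uniform(0.5, 10)
            d = ClimateDay(date(2015, 1, 1) + __import__("datetime").timedelta(days=i), mid + half, mid - half)
            days.append(d)
            mx, mn = max(mx, d.tmax), min(mn, d.tmin)
            dmts.append(d.dmt()), dtrs.append(d.dtr())
        cs = climate_summary(ClimateSeries("x", days))
        assert cs.max_tmax == round(mx, 1) and cs.min_tmin == round(mn, 1)
        assert cs.mean_dmt == round(float(np.mean(dmts)), 1)
        assert cs.max_dtr == round(float(np.max(dtrs)), 1)


def _uniform_precip_series(year, mm_per_day=1.0, july_total=None):
    days = []
    d = date(year, 1, 1)
    while d.year == year:
        p = mm_per_day
        if july_total is not None:
            p = july_total / 31 if d.month == 7 else 0.0
        days.append(ClimateDay(d, 10.0, 0.0, precip=p))
        d += __import__("datetime").timedelta(days=1)
    return ClimateSeries("x", days)


class TestPrecipitation:
    def test_all_precipitation_in_july(self):
        series = _uniform_precip_series(2015, july_total=348.13)
        monthly = monthly_precipitation(series)
        assert monthly[6] == pytest.approx(348.13)
        assert np.all(monthly[[0, 1, 2, 3, 4, 5, 7, 8, 9, 10, 11]] == 0)

    def test_uniform_rain_gives_day_counts(self):
        monthly = monthly_precipitation(_uniform_precip_series(2015))
        expected = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
        np.testing.assert_allclose(monthly, expected)

    def test_matches_groupby_oracle_across_years(self):
        rng = np.random.default_rng(1)
        days = []
        d = date(2015, 1, 1)
        totals = {}
        while d < date(2017, 1, 1):
            p = float(rng.exponential(3.0))
            days.append(ClimateDay(d, 10.0, 0.0, precip=p))
            totals[(d.year, d.month)] = totals.get((d.year, d.month), 0.0) + p
            d += __import__("datetime").timedelta(days=1)
        monthly = monthly_precipitation(ClimateSeries("x", days))
        for month in range(1, 13):
            expected = np.mean([totals[(y, month)] for y in (2015, 2016)])
            assert monthly[month - 1] == pytest.approx(expected)


class TestRainySeason:
    def test_printed_monthly_means_flag_july(self):
        rainy = detect_rainy_season(GARIWANG_MONTHLY_PRECIP)
        assert rainy.month == 7 and rainy.is_rainy
        assert rainy.ratio_to_previous == pytest.approx(348.13 / 101.75)

    def test_flat_series_not_flagged(self):
        rainy = detect_rainy_season([50.0] * 12)
        assert not rainy.is_rainy

    def test_max_month_matches_argmax(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            m = rng.uniform(1, 100, size=12)
            assert detect_rainy_season(m).month == int(np.argmax(m)) + 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            detect_rainy_season([0.0] * 12)


class TestSowingWindow:
    def test_may_start_july_rains(self):
        start, end = sowing_window(ref_doy(date(2001, 5, 21)), rainy_month=7, year=2001)
        assert (start, end) == (date(2001, 5, 21), date(2001, 5, 31))

    def test_june_start_august_rains(self):
        start, end = sowing_window(ref_doy(date(2001, 6, 10)), rainy_month=8, year=2001)
        assert (start, end) == (date(2001, 6, 10), date(2001, 6, 30))

    def test_start_after_cutoff_rejected(self):
        with pytest.raises(ValidationError, match="no valid sowing window"):
            sowing_window(ref_doy(date(2001, 7, 15)), rainy_month=7, year=2001)
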