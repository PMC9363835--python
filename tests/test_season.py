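import numpy as np
import pandas as pd
import pytest

from yieldgap import season
from yieldgap.errors import ValidationError

from conftest import make_year


def linear_limb_profile():
    """p = 1 through DOY 100, ramp to 0 at 110, 0 to 290, ramp to 1 at 300."""
    p = np.ones(365)
    for d in range(1, 366):
        if d <= 100:
            p[d - 1] = 1.0
        elif d < 110:
            p[d - 1] = 1.0 - (d - 100) / 10.0
        elif d <= 290:
            p[d - 1] = 0.0
        elif d < 300:
            p[d - 1] = (d - 290) / 10.0
        else:
            p[d - 1] = 1.0
    # make every value a multiple of 1/10 as a 10-year profile would be
    return season.DOYProbabilityProfile("99001", p, n_years=10)


def multi_year_frame(tav_by_year_doy, years=range(2001, 2011)):
    """Build a gap-free multi-year series with prescribed daily means."""
    frames = []
    for yr in years:
        f = make_year(year=yr)
        doy = season.doy_index(f["date"])
        tav = np.array([tav_by_year_doy(yr, d) for d in doy])
        f["tmax"] = tav + 5.0
        f["tmin"] = tav - 5.0
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


class TestDailyGdd:
    @pytest.mark.parametrize(
        "tmax,tmin,truncate,expected",
        [(20, 10, False, 10.0), (6, 0, False, -2.0), (6, 0, True, 0.0), (5, 5, False, 0.0), (5, 5, True, 0.0)],
    )
    def test_values(self, tmax, tmin, truncate, expected):
        assert season.daily_gdd(tmax, tmin, truncate=truncate) == expected

    def test_inverted_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            season.daily_gdd(5, 10)


class TestProbabilityProfile:
    def test_warm_day_has_zero_probability(self):
        series = multi_year_frame(lambda yr, d: 15.0)
        prof = season.doy_probability_profile(series)
        assert prof.p[180 - 1] == 0.0
        assert prof.n_years == 10

    def test_cold_in_two_of_ten_years_gives_p02(self):
        series = multi_year_frame(
            lambda yr, d: 3.0 if (d == 100 and yr in (2001, 2002)) else 15.0
        )
        prof = season.doy_probability_profile(series)
        assert prof.p[100 - 1] == pytest.approx(0.2)

    def test_matches_bruteforce_count(self):
        rng = np.random.default_rng(12)
        noise = {}

        def tav(yr, d):
            key = (yr, d)
            if key not in noise:
                noise[key] = rng.normal(0, 2)
            return 12.0 - 15.0 * np.cos(2 * np.pi * (d - 15) / 365.0) + noise[key]

        series = multi_year_frame(tav, years=range(2001, 2006))
        prof = season.doy_probability_profile(series)
        # independent oracle: plain loop over (year, DOY)
        for d in (30, 90, 105, 200, 300, 360):
            cold = sum(1 for yr in range(2001, 2006) if tav(yr, d) < 5.0)
            assert prof.p[d - 1] == pytest.approx(cold / 5)

    def test_feb29_dropped_and_mar1_is_doy_60(self):
        # 2004 is a leap year; make Feb 29 freezing, Mar 1 warm, in all years
        def tav(yr, d):
            return 15.0

        frames = []
        for yr in (2003, 2004):
            dates = pd.date_range(f"{yr}-01-01", f"{yr}-12-31", freq="D")
            f = pd.DataFrame(
                {"fips": "99001", "state": "XX", "date": dates, "tmax": 20.0, "tmin": 10.0, "prcp": 0.0, "filled": False}
            )
            frames.append(f)
        series = pd.concat(frames, ignore_index=True)
        # freeze only Feb 29
        mask = (series["date"].dt.month == 2) & (series["date"].dt.day == 29)
        series.loc[mask, ["tmax", "tmin"]] = [-5.0, -10.0]
        prof = season.doy_probability_profile(series)
        assert prof.p.sum() == 0.0  # Feb 29 never counted
        doy = season.doy_index(series["date"])
        mar1 = series["date"].dt.strftime("%m-%d") == "03-01"
        assert set(doy[mar1]) == {60}

    def test_gap_raises_with_location(self):
        series = multi_year_frame(lambda yr, d: 15.0).drop(index=400)
        with pytest.raises(ValidationError, match="gap"):
            season.doy_probability_profile(series)

    def test_profile_conservation(self):
        rng = np.random.default_rng(3)
        years = (2001, 2002, 2003, 2005, 2006)  # no leap years
        vals = {
            (yr, d): 12.0 - 15.0 * np.cos(2 * np.pi * (d - 15) / 365.0) + rng.normal(0, 3)
            for yr in years
            for d in range(1, 366)
        }
        series = multi_year_frame(lambda yr, d: vals[(yr, d)], years=years)
        prof = season.doy_probability_profile(series)
        total_cold = sum(1 for v in vals.values() if v < 5.0)
        assert prof.p.sum() * prof.n_years == pytest.approx(total_cold)


class TestDelineation:
    def test_linear_limbs_cross_at_08_of_ramp(self):
        gs = season.delineate_season(linear_limb_profile())
        assert (gs.start_doy, gs.end_doy, gs.length) == (108, 292, 184)
        assert gs.spring_fit[0] < 0 < gs.fall_fit[0]

    def test_all_zero_profile_is_year_round_sentinel(self):
        prof = season.DOYProbabilityProfile("99001", np.zeros(365), 10)
        gs = season.delineate_season(prof)
        assert gs.status == "year_round"
        assert (gs.start_doy, gs.end_doy) == (1, 365)

    def test_never_warm_profile_is_no_season_sentinel(self):
        prof = season.DOYProbabilityProfile("99001", np.ones(365), 10)
        assert season.delineate_season(prof).status == "no_season"

    def test_threshold_monotonicity(self):
        prof = linear_limb_profile()
        prev = season.delineate_season(prof, 0.1)
        for thr in (0.2, 0.3, 0.5):
            cur = season.delineate_season(prof, thr)
            assert cur.start_doy <= prev.start_doy
            assert cur.end_doy >= prev.end_doy
            prev = cur

    def test_noise_free_crossing_below_half_day(self):
        # exactly linear limbs: fitted crossing equals analytic crossing
        gs = season.delineate_season(linear_limb_profile(), 0.2)
        slope, intercept = gs.spring_fit
        assert abs((0.2 - intercept) / slope - 108.0) < 0.5

    def test_longest_zero_run_wins_over_false_spring(self):
        p = np.ones(365)
        p[59:65] = 0.0  # 6-day false spring in March
        p[119:280] = 0.0  # real season
        p[100] = 0.5  # shoulder point
        prof = season.DOYProbabilityProfile("99001", p, 10)
        gs = season.delineate_season(prof)
        assert 100 < gs.start_doy <= 120
        assert gs.end_doy >= 280


class TestSeasonLength:
    @pytest.mark.parametrize("start,end,expected", [(91, 309, 218), (73, 314, 241), (120, 121, 1)])
    def test_length(self, start, end, expected):
        gs = season.GrowingSeason("99001", start, end)
        assert season.season_length(gs) == expected
        assert gs.length == expected


class TestSummarize:
    def toy_series(self):
        f = make_year()
        doy = season.doy_index(f["date"])
        sel = (doy >= 100) & (doy <= 102)
        f.loc[sel, "prcp"] = [10.0, 0.0, 5.0]
        f.loc[sel, "tmax"] = [20.0, 22.0, 18.0]
        f.loc[sel, "tmin"] = [10.0, 12.0, 8.0]
        return f

    def test_hand_arithmetic(self):
        gs = season.GrowingSeason("99001", 100, 102)
        s = season.summarize_season(self.toy_series(), gs)
        assert s["gsr"] == 15.0
        assert s["tmax_mean"] == 20.0
        assert s["tmin_mean"] == 10.0
        assert s["gdd_sum"] == 30.0
        assert s["tav_mean"] == 15.0

    def test_dry_season_gsr_zero(self):
        f = make_year(prcp=0.0)
        s = season.summarize_season(f, season.GrowingSeason("99001", 100, 200))
        assert s["gsr"] == 0.0

    def test_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(8)
        f = make_year()
        f["tmax"] = rng.uniform(10, 30, len(f))
        f["tmin"] = f["tmax"] - rng.uniform(2, 12, len(f))
        f["prcp"] = rng.gamma(0.7, 10, len(f))
        gs = season.GrowingSeason("99001", 90, 300)
        s = season.summarize_season(f, gs)
        doy = season.doy_index(f["date"])
        gsr = gdd = 0.0
        tmaxs, tmins = [], []
        for i in range(len(f)):
            if 90 <= doy[i] <= 300:
                gsr += f["prcp"].iloc[i]
                g = (f["tmax"].iloc[i] + f["tmin"].iloc[i]) / 2 - 5
                gdd += max(0.0, g)
                tmaxs.append(f["tmax"].iloc[i])
                tmins.append(f["tmin"].iloc[i])
        assert s["gsr"] == pytest.approx(gsr)
        assert s["gdd_sum"] == pytest.approx(gdd)
        assert s["tmax_mean"] == pytest.approx(np.mean(tmaxs))
        assert s["tmin_mean"] == pytest.approx(np.mean(tmins))

    def test_additive_split_at_interior_doy(self):
        rng = np.random.default_rng(9)
        f = make_year()
        f["prcp"] = rng.gamma(0.7, 10, len(f))
        whole = season.summarize_season(f, season.GrowingSeason("99001", 90, 300))
        left = season.summarize_season(f, season.GrowingSeason("99001", 90, 180))
        right = season.summarize_season(f, season.GrowingSeason("99001", 181, 300))
        assert left["gsr"] + right["gsr"] == pytest.approx(whole["gsr"])
        assert left["gdd_sum"] + right["gdd_sum"] == pytest.approx(whole["gdd_sum"])

    def test_missing_season_day_raises(self):
        f = make_year().drop(index=120).reset_index(drop=True)
        with pytest.raises(ValidationError, match="missing"):
            season.summarize_season(f, season.GrowingSeason("99001", 90, 300))
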