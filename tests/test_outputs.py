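import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aedespop.outputs import (OvitrapSeries, adult_peak, annual_outputs,
                              attack_rate, parity_rate, relative_series,
                              validate_against_ovitraps)

from conftest import make_result


def _traj(year=2010, **series):
    """Build a one-year daily trajectory with given series (defaults zero)."""
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    n = len(idx)
    cols = ["E", "L", "P", "A_em", "A1h", "A1g", "A1o",
            "A2h", "A2g", "A2o", "E_l", "A_total", "A_h", "favorable"]
    df = pd.DataFrame(0.0, index=idx, columns=cols)
    df.index.name = "date"
    df["favorable"] = True
    for key, val in series.items():
        df[key] = val
    if "A_total" not in series:
        df["A_total"] = df[["A_em", "A1h", "A1g", "A1o",
                            "A2h", "A2g", "A2o"]].sum(axis=1)
    if "A_h" not in series:
        df["A_h"] = df["A1h"] + df["A2h"]
    return df


class TestAdultPeak:
    def test_all_zero_ties_break_earliest(self):
        res = make_result(_traj())
        value, date = adult_peak(res, 2010)
        assert value == 0.0
        assert date == pd.Timestamp("2010-01-01")

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        a = rng.gamma(2.0, 50.0, 365)
        res = make_result(_traj(A1h=a))
        value, date = adult_peak(res, 2010)
        best = max(range(365), key=lambda i: a[i])
        assert value == a[best]
        assert date == res.data.index[best]

    def test_uncovered_year_rejected(self):
        with pytest.raises(ValueError, match="2011"):
            adult_peak(make_result(_traj()), 2011)


class TestAttackRate:
    def test_constant_series(self):
        res = make_result(_traj(A1h=7.0, A1g=1.0))
        assert attack_rate(res, 2010) == pytest.approx(7.0)

    def test_triangular_profile_hand_mean(self):
        # A_h ramps 0,1,2,...,20 around a peak on 1 July, zero elsewhere
        a = np.zeros(365)
        peak_i = 181  # 1 July
        tri = np.concatenate([np.arange(11), np.arange(9, -1, -1)])
        a[peak_i - 10: peak_i + 11] = tri
        res = make_result(_traj(A1h=a, A_total=a))
        assert attack_rate(res, 2010) == pytest.approx(tri.mean())

    def test_truncates_at_year_end(self):
        # adults peak on 31 December: window is 11 days long, not 21
        a = np.zeros(365)
        a[-11:] = np.arange(11)
        res = make_result(_traj(A1h=a, A_total=a))
        assert attack_rate(res, 2010) == pytest.approx(np.arange(11).mean())

    def test_zero_adults(self):
        assert attack_rate(make_result(_traj()), 2010) == 0.0


class TestParityRate:
    def test_no_parous_females(self):
        res = make_result(_traj(A1h=5.0))
        assert parity_rate(res, 2010) == 0.0

    def test_symmetric_half(self):
        res = make_result(_traj(A1h=3.0, A2h=3.0))
        assert parity_rate(res, 2010) == pytest.approx(0.5)

    def test_emerging_females_count_in_denominator(self):
        res = make_result(_traj(A_em=2.0, A1h=1.0, A2h=1.0))
        assert parity_rate(res, 2010) == pytest.approx(0.25)

    def test_only_favorable_season_counts(self):
        fav = np.zeros(365, dtype=bool)
        fav[100:200] = True
        parous = np.zeros(365)
        parous[150] = 10.0        # inside the season
        nulli = np.zeros(365)
        nulli[150] = 10.0
        nulli[300] = 1000.0       # outside the season, must be ignored
        res = make_result(_traj(A2h=parous, A1h=nulli, favorable=fav))
        assert parity_rate(res, 2010) == pytest.approx(0.5)

    def test_empty_population(self):
        assert parity_rate(make_result(_traj()), 2010) == 0.0


class TestRelativeSeries:
    def test_examples(self):
        np.testing.assert_allclose(relative_series([1, 2, 4]),
                                   [0.25, 0.5, 1.0])
        np.testing.assert_allclose(relative_series([3.0, 3.0]), [1.0, 1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_series([0.0, 0.0])

    def test_idempotent(self):
        x = np.array([0.5, 2.0, 8.0])
        np.testing.assert_allclose(relative_series(relative_series(x)),
                                   relative_series(x))

    @given(st.floats(min_value=0.01, max_value=1e6))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        x = np.array([1.0, 5.0, 2.0])
        np.testing.assert_allclose(relative_series(k * x),
                                   relative_series(x), rtol=1e-12)


class TestOvitrapValidation:
    @staticmethod
    def _result_with_el(el):
        return make_result(_traj(E_l=el))

    @staticmethod
    def _traps(dates, values):
        return OvitrapSeries(pd.DatetimeIndex(dates), np.asarray(values))

    def test_identical_series_r_one(self):
        el = np.abs(np.sin(np.arange(365) / 30.0)) * 100
        res = self._result_with_el(el)
        dates = pd.date_range("2010-05-01", periods=8, freq="14D")
        obs = el[[d.dayofyear - 1 for d in dates]]
        assert validate_against_ovitraps(res, self._traps(dates, obs)) == \
            pytest.approx(1.0)

    def test_mirrored_series_r_minus_one(self):
        el = np.linspace(1, 100, 365)
        res = self._result_with_el(el)
        dates = pd.date_range("2010-05-01", periods=6, freq="14D")
        obs = 200.0 - el[[d.dayofyear - 1 for d in dates]]
        assert validate_against_ovitraps(res, self._traps(dates, obs)) == \
            pytest.approx(-1.0)

    def test_five_point_textbook_pearson(self):
        el = np.zeros(365)
        days = [120, 134, 148, 162, 176]
        sim = np.array([10.0, 40.0, 25.0, 60.0, 50.0])
        el[days] = sim
        obs = np.array([2.0, 9.0, 4.0, 11.0, 12.0])
        dates = [pd.Timestamp("2010-01-01") + pd.Timedelta(days=d)
                 for d in days]
        res = self._result_with_el(el)
        # textbook formula on the relative series (scale cancels)
        x, y = obs / obs.max(), sim / sim.max()
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        r = validate_against_ovitraps(res, self._traps(dates, obs))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_scaling_invariance(self):
        el = np.abs(np.cos(np.arange(365) / 20.0)) * 50 + 1
        res_small = self._result_with_el(el)
        res_big = self._result_with_el(el * 1234.5)
        dates = pd.date_range("2010-04-01", periods=10, freq="10D")
        obs = np.linspace(5, 50, 10)
        traps = self._traps(dates, obs)
        assert validate_against_ovitraps(res_small, traps) == pytest.approx(
            validate_against_ovitraps(res_big, traps), abs=1e-12)

    def test_too_few_dates_rejected(self):
        res = self._result_with_el(np.arange(365.0))
        traps = self._traps(pd.DatetimeIndex(["2010-05-01", "2010-06-01"]),
                            [1.0, 2.0])
        with pytest.raises(ValueError, match="3 collection dates"):
            validate_against_ovitraps(res, traps)

    def test_zero_variance_rejected(self):
        res = self._result_with_el(np.full(365, 5.0))
        dates = pd.date_range("2010-05-01", periods=4, freq="14D")
        with pytest.raises(ValueError, match="zero variance"):
            validate_against_ovitraps(res, self._traps(dates, [1, 2, 3, 4]))

    def test_accumulate_mode_sums_between_visits(self):
        el = np.ones(365)
        res = self._result_with_el(el)
        dates = pd.DatetimeIndex(["2010-01-14", "2010-01-28", "2010-02-25"])
        obs = np.array([14.0, 14.0, 28.0])  # exactly the accumulated sums
        r = validate_against_ovitraps(res, self._traps(dates, obs),
                                      accumulate=True)
        assert r == pytest.approx(1.0)

    def test_csv_reader_splits_sites(self, tmp_path):
        path = tmp_path / "traps.csv"
        path.write_text(
            "date,mean_eggs_per_trap,site\n"
            "2010-05-01,10,nice\n2010-05-15,20,nice\n"
            "2010-05-01,5,biot\n2010-05-15,9,biot\n")
        series = OvitrapSeries.from_csv(path)
        assert {s.site for s in series} == {"nice", "biot"}
        assert all(len(s) == 2 for s in series)


def test_annual_outputs_on_simulation(result4):
    table = annual_outputs(result4)
    assert list(table.index) == [2008, 2009, 2010, 2011]
    assert ((table["parity_rate"] >= 0) & (table["parity_rate"] <= 1)).all()
    assert (table["attack_rate"] <= table["adult_peak"]).all()
    assert (table["adult_peak"] > 0).all()
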