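import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dielflux import GeneratorConfig, SiteMeta, generate_site
from dielflux.diel import (FitError, adjust_to_mean_temp, daily_means,
                           diel_test, fit_temp_response, TempResponseFit)
from dielflux.solar import label_hours

from conftest import make_labeled


def _labeled_hours(day_vals, night_vals, date=dt.date(2019, 6, 1)):
    rows = []
    for period, vals in (("day", day_vals), ("night", night_vals)):
        for i, v in enumerate(vals):
            rows.append({"timestamp": pd.Timestamp(date) + pd.Timedelta(hours=i),
                         "rs": v, "ts": 18.0, "swc": 25.0,
                         "period": period, "diel_date": date})
    return pd.DataFrame(rows)


class TestDailyMeans:
    def test_arithmetic(self):
        d = daily_means(_labeled_hours([1, 2, 3], [2, 3, 4]))
        assert d["day_mean_rs"].iloc[0] == 2.0
        assert d["night_mean_rs"].iloc[0] == 3.0
        assert d["n_day_hours"].iloc[0] == 3

    def test_constant_series(self):
        d = daily_means(_labeled_hours([2.0] * 5, [2.0] * 5))
        assert d["day_mean_rs"].iloc[0] == d["night_mean_rs"].iloc[0] == 2.0

    def test_lagged_generator_night_exceeds_day_most_days(self, noiseless_run):
        lab, _ = noiseless_run
        d = daily_means(lab)
        assert (d["night_mean_rs"] > d["day_mean_rs"]).mean() > 0.5


class TestDielTest:
    @staticmethod
    def _daily(day, night):
        return pd.DataFrame({
            "day_mean_rs": day, "night_mean_rs": night,
            "day_mean_ts": 18.0, "night_mean_ts": 18.0})

    def test_identical_series_not_significant(self):
        s = self._daily([2.0] * 30, [2.0] * 30)
        r = diel_test(s, "rs")
        assert (r.t_stat, r.p_value, r.significance) == (0.0, 1.0, "ns")

    def test_exact_shift_is_maximally_significant(self):
        day = list(np.linspace(1, 3, 30))
        r = diel_test(self._daily(day, [d + 0.5 for d in day]), "rs")
        assert r.significance == "pos"
        assert r.p_value == pytest.approx(0.0, abs=1e-12)
        assert r.delta == pytest.approx(0.5)

    def test_small_n_flags_low_n(self):
        r = diel_test(self._daily([1, 2, 3], [3, 2, 1]), "rs")
        assert r.significance == "ns" and r.low_n

    def test_percent_delta_definition(self):
        r = diel_test(self._daily([2.0] * 10, [2.2] * 10), "rs")
        assert r.percent_delta == pytest.approx(10.0)

    def test_sem_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(0)
        day = rng.normal(2.0, 0.3, size=200)
        night = day + rng.normal(0.2, 0.25, size=200)
        r = diel_test(self._daily(day, night), "rs")
        diffs = night - day
        boots = rng.choice(diffs, size=(2000, diffs.size)).mean(axis=1)
        assert r.sem == pytest.approx(boots.std(ddof=1), rel=0.10)


class TestFitTempResponse:
    @staticmethod
    def _exp_frame(rs0, beta, n=200, seed=None, cv=0.0, ts_lo=5.0, ts_hi=25.0):
        ts = np.linspace(ts_lo, ts_hi, n)
        rs = rs0 * np.exp(beta * ts)
        if cv:
            rng = np.random.default_rng(seed)
            s2 = np.log1p(cv ** 2)
            rs = rs * rng.lognormal(-s2 / 2, np.sqrt(s2), size=n)
        return pd.DataFrame({"rs": rs, "ts": ts})

    def test_noiseless_inversion_recovers_parameters(self):
        fit = fit_temp_response(self._exp_frame(1.5, np.log(2) / 10))
        assert fit.rs0 == pytest.approx(1.5, abs=1e-9)
        assert fit.beta == pytest.approx(0.0693147, abs=1e-6)
        assert fit.q10 == pytest.approx(2.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_response_gives_unit_q10_with_ci_cover(self):
        fit = fit_temp_response(self._exp_frame(2.0, 0.0, seed=3, cv=0.1))
        assert fit.q10 == pytest.approx(1.0, abs=0.1)
        assert abs(fit.beta) < 2 * fit.se_beta

    def test_q10_is_exactly_exp_ten_beta(self):
        fit = fit_temp_response(self._exp_frame(1.0, 0.123))
        assert fit.q10 == np.exp(10 * fit.beta)

    def test_parameter_recovery_q10_2p5_under_noise(self):
        hits = 0
        beta = np.log(2.5) / 10
        for seed in range(50):
            fit = fit_temp_response(self._exp_frame(1.0, beta, n=1500,
                                                    seed=seed, cv=0.10))
            hits += 2.3 <= fit.q10 <= 2.7
        assert hits >= 45

    def test_log_and_nonlinear_fits_agree_under_moderate_noise(self):
        df = self._exp_frame(1.2, np.log(2) / 10, n=800, seed=7, cv=0.15)
        log_fit = fit_temp_response(df)
        nls_fit = fit_temp_response(df, method="nls")
        assert nls_fit.q10 == pytest.approx(log_fit.q10, rel=0.05)

    def test_zero_temperature_variance_errors(self):
        df = pd.DataFrame({"rs": [1.0] * 40, "ts": [18.0] * 40})
        with pytest.raises(FitError, match="temperature range"):
            fit_temp_response(df)

    def test_too_few_hours_errors(self):
        with pytest.raises(FitError, match="hours"):
            fit_temp_response(self._exp_frame(1.0, 0.07, n=10))


class TestAdjustToMeanTemp:
    @staticmethod
    def _fit(q10, period):
        return TempResponseFit("s", period, 1.0, np.log(q10) / 10, 0.0, 1.0, 100)

    def test_identity_at_reference_temperature(self):
        daily = pd.DataFrame({"day_mean_rs": [2.0], "night_mean_rs": [3.0],
                              "day_mean_ts": [18.0], "night_mean_ts": [18.0]})
        adj = adjust_to_mean_temp(daily, self._fit(2.0, "day"),
                                  self._fit(2.5, "night"), 18.0)
        assert adj["day_rs_adj"].iloc[0] == 2.0
        assert adj["night_rs_adj"].iloc[0] == 3.0

    def test_one_decade_doubles_flux_at_q10_2(self):
        daily = pd.DataFrame({"day_mean_rs": [1.0], "night_mean_rs": [1.0],
                              "day_mean_ts": [8.0], "night_mean_ts": [8.0]})
        adj = adjust_to_mean_temp(daily, self._fit(2.0, "day"),
                                  self._fit(2.0, "night"), 18.0)
        assert adj["day_rs_adj"].iloc[0] == pytest.approx(2.0)

    def test_missing_fit_errors(self):
        with pytest.raises(FitError):
            adjust_to_mean_temp(pd.DataFrame(), None, self._fit(2, "night"), 18.0)

    def test_lag_driven_night_excess_survives_adjustment(self, noiseless_run):
        lab, _ = noiseless_run
        d = daily_means(lab)
        fd = fit_temp_response(lab, "day")
        fn = fit_temp_response(lab, "night")
        adj = adjust_to_mean_temp(d, fd, fn, float(lab["ts"].mean()))
        assert adj["night_rs_adj"].mean() > adj["day_rs_adj"].mean()

    def test_adjustment_removes_pure_temperature_artifact(self):
        # only asymmetry: Ts phase (peak at solar noon); equal betas, no lag
        hits = 0
        for seed in range(100):
            lab = make_labeled(GeneratorConfig(
                seed=900 + seed, base_root=0.0, priming_coef=0.0,
                Ts_phase_lag=0.0, lag_mean=0.0))
            d = daily_means(lab)
            adj = adjust_to_mean_temp(d, fit_temp_response(lab, "day"),
                                      fit_temp_response(lab, "night"),
                                      float(lab["ts"].mean()))
            adj = adj.rename(columns={"day_rs_adj": "day_mean_rs_adj",
                                      "night_rs_adj": "night_mean_rs_adj"})
            hits += diel_test(adj, "rs_adj").significance == "ns"
        assert hits >= 90
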