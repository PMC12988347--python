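import datetime as dt
import hashlib

import numpy as np
import pandas as pd
import pytest

from dielflux import GeneratorConfig, SiteMeta, generate_site, write_cosore_like
from dielflux.solar import PolarDayError, label_hours
from dielflux.synthetic import _gamma_kernel

from conftest import make_labeled


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(Ts_amplitude=-1), dict(lag_mean=-2), dict(noise_cv=-0.1),
        dict(start_date=dt.date(2019, 9, 1)), dict(lag_shape=0),
        dict(gpp_day_ar1=1.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)

    def test_truth_q10_is_exp_ten_beta(self):
        cfg = GeneratorConfig(seed=0, beta_root=0.05, beta_het=0.12)
        _, _, truth = generate_site(cfg)
        assert truth.true_Q10_root == pytest.approx(np.exp(0.5), rel=1e-12)
        assert truth.true_Q10_het == pytest.approx(np.exp(1.2), rel=1e-12)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a, ga, _ = generate_site(GeneratorConfig(seed=11))
        b, gb, _ = generate_site(GeneratorConfig(seed=11))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ga, gb)

    def test_different_seeds_differ(self):
        a, _, _ = generate_site(GeneratorConfig(seed=1))
        b, _, _ = generate_site(GeneratorConfig(seed=2))
        assert not np.allclose(a["rs"], b["rs"])

    def test_batch_of_written_files_reproducible(self, tmp_path):
        def digest(root):
            h = hashlib.sha256()
            for i in range(3):
                cfg = GeneratorConfig(seed=1 + i)
                flux, _, _ = generate_site(cfg)
                meta = SiteMeta(f"S{i}", cfg.site_lat, cfg.site_lon,
                                cfg.utc_offset, "MF")
                paths = write_cosore_like(flux, root, meta)
                h.update(paths["flux"].read_bytes())
            return h.hexdigest()

        assert digest(tmp_path / "a") == digest(tmp_path / "b")


class TestGeneratorPhysics:
    def test_mass_consistency_with_noise_off(self, noiseless_run):
        lab, _ = noiseless_run
        np.testing.assert_array_equal(lab["rs"].to_numpy(),
                                      (lab["rroot"] + lab["rh"]).to_numpy())

    def test_fluxes_nonnegative(self, mechanism_run):
        lab, _, _ = mechanism_run
        assert (lab[["rs", "rroot", "rh", "gpp"]] >= 0).all().all()

    def test_flattened_drivers_give_constant_flux(self):
        lab = make_labeled(GeneratorConfig(
            seed=0, noise_cv=0.0, lag_mean=0.0, priming_coef=0.0,
            beta_root=0.0, beta_het=0.0, base_root=0.0, Ts_synoptic_sd=0.0))
        assert lab["rs"].nunique() == 1
        day = lab.loc[lab["period"] == "day", "rs"].mean()
        night = lab.loc[lab["period"] == "night", "rs"].mean()
        assert day == pytest.approx(night, rel=1e-12)

    def test_warmer_day_means_larger_day_flux_without_lag(self):
        # monotone exponential: Ts peak at solar noon, no substrate coupling
        lab = make_labeled(GeneratorConfig(
            seed=0, noise_cv=0.0, lag_mean=0.0, base_root=0.0,
            Ts_phase_lag=0.0, Ts_synoptic_sd=0.0))
        day = lab.loc[lab["period"] == "day"]
        night = lab.loc[lab["period"] == "night"]
        assert day["ts"].mean() > night["ts"].mean()
        assert day["rs"].mean() > night["rs"].mean()

    def test_eight_hour_lag_elevates_night_flux(self):
        # the headline mechanism: substrate arrives after dark
        lab = make_labeled(GeneratorConfig(seed=5, noise_cv=0.0,
                                           Ts_phase_lag=2.0))
        assert (lab.loc[lab["period"] == "night", "rs"].mean()
                > lab.loc[lab["period"] == "day", "rs"].mean())

    def test_lag_placement_by_cross_correlation(self):
        cfg = GeneratorConfig(seed=3, noise_cv=0.0, lag_mean=8.0, lag_shape=6.0,
                              base_het=0.0, priming_coef=0.0)
        flux, _, _ = generate_site(cfg)
        detrended = flux["rs"] / np.exp(cfg.beta_root * flux["ts"])
        gpp = flux["gpp"].to_numpy()
        lags = np.arange(0, 16)
        cors = [np.corrcoef(detrended[l:], gpp[:len(gpp) - l or None])[0, 1]
                for l in lags]
        assert abs(lags[int(np.argmax(cors))] - cfg.lag_mean) <= 1

    def test_null_config_mean_difference_is_zero(self):
        # phase-symmetric Ts, no substrate coupling: day-night difference is noise
        meta = SiteMeta("N", 0.0, 0.0, 0.0, "MF")
        diffs = []
        for seed in range(100):
            flux, _, _ = generate_site(GeneratorConfig.null(seed=seed))
            lab = label_hours(flux, meta)
            diffs.append(lab.loc[lab["period"] == "night", "rs"].mean()
                         - lab.loc[lab["period"] == "day", "rs"].mean())
        diffs = np.asarray(diffs)
        sem = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 2 * sem

    def test_polar_summer_dates_error_names_date(self):
        with pytest.raises(PolarDayError, match="2019-06"):
            generate_site(GeneratorConfig(site_lat=75.0, seed=0))


class TestKernel:
    def test_unit_mass_and_mean(self):
        k = _gamma_kernel(8.0, 6.0)
        assert k.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.arange(k.size) @ k == pytest.approx(8.0, abs=0.3)

    def test_zero_lag_is_identity_kernel(self):
        k = _gamma_kernel(0.0, 6.0)
        assert k[0] == 1.0 and k[1:].sum() == 0.0


class TestGppDaily:
    def test_daily_totals_are_integrated_hourly_flux(self, mechanism_run):
        lab, gpp_daily, _ = mechanism_run
        hourly = lab.assign(date=pd.to_datetime(lab["timestamp"]).dt.date) \
            .groupby("date")["gpp"].sum() * 3600 * 12e-6
        merged = gpp_daily.set_index("date")["gpp"]
        np.testing.assert_allclose(merged.to_numpy(), hourly.to_numpy(), rtol=1e-9)
        assert merged.max() < 30  # plausible g C m-2 d-1 for a forest


class TestMinuteResolutionOracle:
    """Re-integrate the generator equations at 1-min resolution and compare
    day/night mean Rs against the hourly implementation (noise off)."""

    def test_day_night_means_match_fine_grid(self):
        cfg = GeneratorConfig(seed=0, noise_cv=0.0, gpp_day_sigma=0.0,
                              Ts_synoptic_sd=0.0,
                              end_date=dt.date(2019, 6, 10))
        flux, _, _ = generate_site(cfg)
        meta = SiteMeta("O", cfg.site_lat, cfg.site_lon, cfg.utc_offset, "MF")
        lab = label_hours(flux, meta)

        from dielflux.solar import _declination_rad, _fractional_year
        from scipy import stats as sps

        # independent minute-grid integration incl. 3 lead-in days
        start = pd.Timestamp(cfg.start_date) - pd.Timedelta(days=3)
        t = pd.date_range(start, pd.Timestamp(cfg.end_date) + pd.Timedelta(days=1),
                          freq="min", inclusive="left")
        clock = t.hour + t.minute / 60.0 + 0.5 / 60.0
        t_solar = clock + cfg.site_lon / 15.0 - cfg.utc_offset
        decl = _declination_rad(_fractional_year(t.dayofyear.to_numpy(float)))
        lat = np.deg2rad(cfg.site_lat)
        sin_elev = (np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl)
                    * np.cos(np.pi * (t_solar - 12) / 12))
        ts = cfg.mean_Ts + cfg.Ts_amplitude * np.sin(
            2 * np.pi * (t_solar - 6 - cfg.Ts_phase_lag) / 24)
        gpp = cfg.gpp_max * np.clip(sin_elev, 0, None)
        grid = np.arange(0, 48 * 60 + 1) / 60.0
        cdf = sps.gamma.cdf(np.append(grid, grid[-1] + 1 / 60.0),
                            a=cfg.lag_shape, scale=cfg.lag_mean / cfg.lag_shape)
        k = np.diff(cdf)
        k /= k.sum()
        substrate = np.convolve(gpp, k)[:len(gpp)]
        rs = (cfg.base_root * substrate * np.exp(cfg.beta_root * ts)
              + cfg.base_het * np.exp(cfg.beta_het * ts))
        keep = np.asarray(t >= pd.Timestamp(cfg.start_date))
        tk, rsk = t[keep], np.asarray(rs)[keep]
        # minute-level day/night labels from per-date sunrise/sunset
        from dielflux.solar import sun_times
        minutes = tk.hour * 60 + tk.minute + 0.5
        windows = {d: sun_times(cfg.site_lat, cfg.site_lon, cfg.utc_offset, d)
                   for d in np.unique(tk.date)}
        rise = np.array([windows[d].sunrise_hours * 60 for d in tk.date])
        sets = np.array([windows[d].sunset_hours * 60 for d in tk.date])
        fine_day = np.asarray((minutes >= rise) & (minutes < sets))

        for period, mask in (("day", fine_day), ("night", ~fine_day)):
            coarse = lab.loc[lab["period"] == period, "rs"].mean()
            ref = rsk[mask].mean()
            assert coarse == pytest.approx(ref, rel=0.02)
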