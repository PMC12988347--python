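"""Synthetic hourly soil-respiration generator with known ground truth.

Emulates a continuous chamber record (Rs, Ts, SWC, optional GPP and Rroot/Rh
partition) driven by the two candidate mechanisms for elevated nighttime soil
respiration:

1. a *photosynthate-supply lag*: canopy carbon fixed during the day reaches
   roots and rhizosphere microbes hours later, through a gamma-shaped
   transport kernel, so root respiration can peak after dark;
2. a *day/night-asymmetric basal rate* and/or asymmetric temperature
   sensitivities of the root and heterotrophic components.

Model, on an hourly grid in site standard time (drivers evaluated at the
midpoint of each hour)::

    Ts(t)    = mean_Ts + A_syn(d) + Ts_amplitude * sin(2*pi*(t_solar - 6h - Ts_phase_lag)/24h)
    GPP(t)   = gpp_max * scale_d * max(0, sin(solar elevation))
    S(t)     = sum_tau k(tau; lag_mean, lag_shape) * GPP(t - tau)   (gamma kernel,
               unit mass over 0-48 h)
    Rroot(t) = base_root * f(t) * S(t) * exp(beta_root * Ts(t))
    Rh(t)    = base_het  * f(t) * (1 + priming_coef * S(t)) * exp(beta_het * Ts(t))
    Rs(t)    = (Rroot + Rh) * eps(t),  eps lognormal, mean 1, CV = noise_cv

where ``scale_d`` is a stationary lognormal AR(1) day-to-day productivity
factor and ``f(t)`` is ``night_basal_factor`` during astronomical night
(solar elevation <= 0) and 1 otherwise. With ``noise_cv = 0`` the identity
``Rs = Rroot + Rh`` holds exactly at every hour.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace, asdict
from math import log
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import SiteMeta, write_site_meta
from .solar import _fractional_year, _declination_rad, sun_times, PolarDayError

__all__ = ["GeneratorConfig", "SynthTruth", "generate_site", "write_cosore_like"]

#: substrate kernel support, hours
KERNEL_SUPPORT_H = 48
#: lead-in discarded so the substrate convolution starts in steady state
SPINUP_DAYS = 3

_SECONDS_PER_HOUR = 3600.0
_G_C_PER_UMOL = 12.0e-6  # umol CO2 -> g C


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters of one synthetic site-season.

    Defaults describe a mid-latitude temperate forest summer: mean 5-cm soil
    temperature 18 degC with a 1.5 degC diel harmonic peaking 4 h after solar
    noon (the diel wave at 5 cm under canopy is strongly damped and delayed
    relative to air temperature), midday canopy uptake of 20 umol m-2 s-1,
    and a photosynthate transport lag averaging 8 h (gamma kernel, shape 6),
    inside the 6-12 h range reported for forest ecosystems. Component
    temperature sensitivities default to Q10 = 2 (beta = ln 2 / 10 per degC).
    """

    site_lat: float = 45.0
    site_lon: float = -90.0
    utc_offset: float = -6.0
    start_date: dt.date = dt.date(2019, 6, 1)
    end_date: dt.date = dt.date(2019, 8, 31)  # inclusive; 92 days
    mean_Ts: float = 18.0          # degC
    Ts_amplitude: float = 1.5      # degC
    Ts_phase_lag: float = 4.0      # h after solar noon
    Ts_synoptic_sd: float = 2.0    # degC, day-scale AR(1) weather anomaly
    Ts_synoptic_ar1: float = 0.8
    gpp_max: float = 20.0          # umol m-2 s-1 at full sun
    gpp_day_ar1: float = 0.7
    gpp_day_sigma: float = 0.3     # log-scale SD of the daily factor
    lag_mean: float = 8.0          # h
    lag_shape: float = 6.0         # gamma shape (>= 1 -> unimodal)
    beta_root: float = log(2.0) / 10.0  # per degC
    beta_het: float = log(2.0) / 10.0
    base_root: float = 0.09        # umol m-2 s-1 per unit substrate
    base_het: float = 0.55         # umol m-2 s-1 baseline
    priming_coef: float = 0.0
    noise_cv: float = 0.1
    swc_mean: float = 25.0         # %
    swc_amplitude: float = 3.0     # %
    night_basal_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.Ts_amplitude < 0 or self.swc_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.lag_mean < 0:
            raise ValueError("lag_mean must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")
        if self.lag_shape <= 0:
            raise ValueError("lag_shape must be > 0")
        if not 0 <= self.gpp_day_ar1 < 1:
            raise ValueError("gpp_day_ar1 must be in [0, 1)")
        if self.Ts_synoptic_sd < 0 or not 0 <= self.Ts_synoptic_ar1 < 1:
            raise ValueError("Ts synoptic anomaly parameters out of range")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "GeneratorConfig":
        """A no-mechanism configuration: no substrate coupling, no lag, equal
        temperature sensitivities, and a soil-temperature harmonic peaking at
        sunset so day and night sample identical Ts distributions (equator).
        Any residual day-night Rs difference is pure noise.
        """
        base = dict(site_lat=0.0, site_lon=0.0, utc_offset=0.0,
                    Ts_phase_lag=6.0, Ts_synoptic_sd=0.0, lag_mean=0.0,
                    base_root=0.0, priming_coef=0.0, night_basal_factor=1.0,
                    seed=seed)
        base.update(kw)
        return cls(**base)


@dataclass(frozen=True)
class SynthTruth:
    """Recoverable ground truth of a generated series (test oracle container)."""

    true_Q10_root: float
    true_Q10_het: float
    lag_mean: float
    expected_sign_dRs: int          # sign of noiseless (night mean - day mean) Rs
    component_keys: tuple = ("rroot", "rh", "gpp")


def _gamma_kernel(lag_mean: float, lag_shape: float) -> np.ndarray:
    """Discrete hourly transport kernel, unit mass on 0..KERNEL_SUPPORT_H."""
    tau = np.arange(KERNEL_SUPPORT_H + 1, dtype=float)
    if lag_mean == 0:
        k = np.zeros_like(tau)
        k[0] = 1.0
        return k
    scale = lag_mean / lag_shape
    # integrate the continuous density over bins centred on integer lags,
    # [tau - 1/2, tau + 1/2), so a lag of tau hours maps midpoint to midpoint
    edges = np.concatenate(([0.0], np.arange(KERNEL_SUPPORT_H + 1) + 0.5))
    cdf = stats.gamma.cdf(edges, a=lag_shape, scale=scale)
    k = np.diff(cdf)
    s = k.sum()
    if s <= 0:
        raise ValueError("degenerate lag kernel")
    return k / s


def generate_site(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Generate one synthetic site record.

    Returns ``(flux, gpp_daily, truth)``: an hourly DataFrame with columns
    ``timestamp, rs, ts, swc, rroot, rh, gpp`` (timestamps label hour starts,
    site standard time), a daily GPP table (``date, gpp`` in g C m-2 day-1),
    and the ground truth. Identical configs give bit-identical output.
    """
    c = config
    # polar screening: every simulated date must have a sunrise and sunset
    if abs(c.site_lat) > 66.0:
        d = c.start_date
        while d <= c.end_date:
            sun_times(c.site_lat, c.site_lon, c.utc_offset, d)  # raises PolarDayError
            d += dt.timedelta(days=1)

    start = pd.Timestamp(c.start_date) - pd.Timedelta(days=SPINUP_DAYS)
    end = pd.Timestamp(c.end_date) + pd.Timedelta(days=1)
    hours = pd.date_range(start, end, freq="h", inclusive="left")
    n = len(hours)
    rng = np.random.default_rng(np.uint32(c.seed))

    # drivers at hour midpoints, solar-local time
    clock = hours.hour.to_numpy(float) + 0.5
    solar_shift = c.site_lon / 15.0 - c.utc_offset
    t_solar = clock + solar_shift
    doy = hours.dayofyear.to_numpy(float)
    decl = _declination_rad(_fractional_year(doy))
    lat_r = np.deg2rad(c.site_lat)
    hour_angle = np.pi * (t_solar - 12.0) / 12.0
    sin_elev = (np.sin(lat_r) * np.sin(decl)
                + np.cos(lat_r) * np.cos(decl) * np.cos(hour_angle))

    day_idx = ((hours.normalize() - start.normalize()).days).to_numpy()
    n_days = day_idx.max() + 1

    # synoptic (weather) soil-temperature anomaly: stationary AR(1) by day,
    # shared by every hour of a calendar day so it cancels in paired diel tests
    syn = np.zeros(n_days)
    if c.Ts_synoptic_sd > 0:
        zs = rng.standard_normal(n_days)
        syn[0] = c.Ts_synoptic_sd * zs[0]
        innov = c.Ts_synoptic_sd * np.sqrt(1.0 - c.Ts_synoptic_ar1 ** 2)
        for d in range(1, n_days):
            syn[d] = c.Ts_synoptic_ar1 * syn[d - 1] + innov * zs[d]

    ts = (c.mean_Ts + syn[day_idx] + c.Ts_amplitude * np.sin(
        2 * np.pi * (t_solar - 6.0 - c.Ts_phase_lag) / 24.0))

    # day-to-day productivity factor: stationary lognormal AR(1)
    z = rng.standard_normal(n_days)
    x = np.empty(n_days)
    x[0] = c.gpp_day_sigma * z[0]
    innov_sd = c.gpp_day_sigma * np.sqrt(1.0 - c.gpp_day_ar1 ** 2)
    for d in range(1, n_days):
        x[d] = c.gpp_day_ar1 * x[d - 1] + innov_sd * z[d]
    scale_d = np.exp(x - 0.5 * c.gpp_day_sigma ** 2)

    gpp = c.gpp_max * scale_d[day_idx] * np.clip(sin_elev, 0.0, None)

    kernel = _gamma_kernel(c.lag_mean, c.lag_shape)
    substrate = np.convolve(gpp, kernel)[:n]

    night_factor = np.where(sin_elev <= 0.0, c.night_basal_factor, 1.0)
    rroot = c.base_root * night_factor * substrate * np.exp(c.beta_root * ts)
    rh = (c.base_het * night_factor * (1.0 + c.priming_coef * substrate)
          * np.exp(c.beta_het * ts))
    rs_clean = rroot + rh
    if c.noise_cv > 0:
        sigma2 = np.log1p(c.noise_cv ** 2)
        eps = rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=n)
        rs = rs_clean * eps
    else:
        rs = rs_clean.copy()

    swc = c.swc_mean + c.swc_amplitude * np.sin(2 * np.pi * (doy - 172.0) / 365.0)

    flux = pd.DataFrame({
        "timestamp": hours.floor("h"), "rs": rs, "ts": ts, "swc": swc,
        "rroot": rroot, "rh": rh, "gpp": gpp,
    })
    keep = flux["timestamp"] >= pd.Timestamp(c.start_date)
    flux = flux.loc[keep].reset_index(drop=True)
    sin_elev = sin_elev[keep.to_numpy()]
    rs_clean = rs_clean[keep.to_numpy()]

    gpp_daily = (flux.assign(date=flux["timestamp"].dt.date)
                 .groupby("date")["gpp"].sum()
                 .mul(_SECONDS_PER_HOUR * _G_C_PER_UMOL)
                 .rename("gpp").reset_index())

    night = sin_elev <= 0.0
    d_mean, n_mean = rs_clean[~night].mean(), rs_clean[night].mean()
    rel = (n_mean - d_mean) / max(d_mean, 1e-12)
    sign = 0 if abs(rel) < 1e-9 else (1 if rel > 0 else -1)
    truth = SynthTruth(true_Q10_root=float(np.exp(10 * c.beta_root)),
                       true_Q10_het=float(np.exp(10 * c.beta_het)),
                       lag_mean=c.lag_mean, expected_sign_dRs=sign)
    return flux, gpp_daily, truth


def write_cosore_like(flux: pd.DataFrame, out_dir, meta: SiteMeta | None = None,
                      *, write_partition: bool = False,
                      gpp_daily: pd.DataFrame | None = None) -> dict:
    """Write a generated series as the CSV/YAML file set the readers ingest.

    Returns a dict of the paths written. The flux CSV round-trips losslessly
    through :func:`dielflux.io.read_flux_table` on the shared columns.
    """
    if flux.empty:
        raise ValueError("refusing to write an empty flux series")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if meta is None:
        meta = SiteMeta(site_id="SYN", lat=45.0, lon=-90.0, utc_offset=-6.0, igbp="MF")

    table = pd.DataFrame({
        "timestamp_iso": pd.to_datetime(flux["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
        "port": flux.get("port", 1),
        "rs_umol_m2_s": flux["rs"],
        "ts_C_5cm": flux["ts"],
        "swc_pct_5cm": flux["swc"],
        "treatment": flux.get("treatment", "none"),
    })
    paths = {}
    flux_path = out_dir / f"{meta.site_id}_flux.csv"
    table.to_csv(flux_path, index=False, float_format="%.10g")
    paths["flux"] = flux_path

    meta_path = out_dir / f"{meta.site_id}_meta.yaml"
    write_site_meta(meta, meta_path)
    paths["meta"] = meta_path

    if write_partition:
        if "rh" not in flux.columns:
            raise ValueError("partition output requested but series has no rh column")
        part = table.copy()
        part["rh_umol_m2_s"] = flux["rh"].to_numpy()
        part_path = out_dir / f"{meta.site_id}_partition.csv"
        part.to_csv(part_path, index=False, float_format="%.10g")
        paths["partition"] = part_path

    if gpp_daily is not None:
        gpp_path = out_dir / f"{meta.site_id}_gpp.csv"
        pd.DataFrame({"date": gpp_daily["date"], "gpp_gC_m2_d": gpp_daily["gpp"]}
                     ).to_csv(gpp_path, index=False, float_format="%.10g")
        paths["gpp"] = gpp_path
    return paths
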