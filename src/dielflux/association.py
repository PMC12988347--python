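"""Model-II (standardized major axis) regression and GPP-linkage analyses.

SMA regression is the symmetric line fit appropriate when both variables
carry error (day vs night fluxes, Rs vs GPP):

    slope = sign(r) * sd(y) / sd(x),   intercept = mean(y) - slope * mean(x)

with the 95% slope CI  slope * (sqrt(B + 1) +- sqrt(B)),
B = F(0.95; 1, n-2) * (1 - r^2) / (n - 2)  — the standard lmodel2/smatr
construction. The lag analysis correlates daily Rs with GPP shifted 0-45
days earlier, probing how long fixed carbon takes to appear as soil efflux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SmaFit", "sma_fit", "day_night_sma", "gpp_lag_profile",
           "LagProfile", "rs_gpp_sma"]

MAX_LAG_DAYS = 45
MIN_PAIRS_PER_LAG = 10


@dataclass(frozen=True)
class SmaFit:
    slope: float
    intercept: float
    r: float
    n: int
    slope_ci_low: float
    slope_ci_high: float

    @property
    def r2(self) -> float:
        return self.r ** 2


@dataclass(frozen=True)
class LagProfile:
    site_id: str
    lags: np.ndarray             # 0..max_lag days
    r_by_lag: np.ndarray         # Pearson r, NaN where < MIN_PAIRS_PER_LAG pairs
    peak_lag: int                # argmax of r, smallest lag on ties
    peak_r: float


def sma_fit(x, y) -> SmaFit:
    """Standardized major axis fit of y on x with a 95% slope CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"SMA needs at least 3 points, got {n}")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("SMA undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    b = stats.f.ppf(0.95, 1, n - 2) * max(0.0, 1.0 - r * r) / (n - 2)
    lo = slope * (np.sqrt(b + 1.0) - np.sqrt(b))
    hi = slope * (np.sqrt(b + 1.0) + np.sqrt(b))
    if slope < 0:
        lo, hi = hi, lo
    return SmaFit(float(slope), intercept, r, n, float(lo), float(hi))


def day_night_sma(site_means: pd.DataFrame, day_col: str = "day_mean_rs",
                  night_col: str = "night_mean_rs") -> SmaFit:
    """Cross-site SMA of nighttime vs daytime mean flux.

    A slope above 1 means the night excess grows with site flux magnitude.
    """
    return sma_fit(site_means[day_col], site_means[night_col])


def gpp_lag_profile(daily_rs: pd.Series, daily_gpp: pd.Series, *,
                    site_id: str = "", max_lag: int = MAX_LAG_DAYS) -> LagProfile:
    """Pearson r between daily Rs and GPP lagged 0..max_lag days earlier.

    Both inputs are indexed by calendar date. r(l) pairs Rs(t) with
    GPP(t - l); pairs with missing values drop per lag and lags with fewer
    than 10 pairs report NaN. The peak is the maximum r, earliest lag on ties.
    """
    rs = pd.Series(daily_rs).copy()
    gpp = pd.Series(daily_gpp).copy()
    rs.index = pd.to_datetime(rs.index)
    gpp.index = pd.to_datetime(gpp.index)
    lags = np.arange(max_lag + 1)
    r_by_lag = np.full(lags.size, np.nan)
    for l in lags:
        shifted = gpp.copy()
        shifted.index = shifted.index + pd.Timedelta(days=int(l))
        pair = pd.concat({"rs": rs, "gpp": shifted}, axis=1).dropna()
        if len(pair) < MIN_PAIRS_PER_LAG:
            continue
        if pair["rs"].std() == 0 or pair["gpp"].std() == 0:
            continue
        r_by_lag[l] = float(np.corrcoef(pair["rs"], pair["gpp"])[0, 1])
    if np.all(np.isnan(r_by_lag)):
        peak_lag, peak_r = -1, np.nan
    else:
        peak_lag = int(np.nanargmax(r_by_lag))  # nanargmax returns first max
        peak_r = float(r_by_lag[peak_lag])
    return LagProfile(site_id, lags, r_by_lag, peak_lag, peak_r)


def rs_gpp_sma(daily: pd.DataFrame, gpp_daily: pd.DataFrame,
               ) -> dict[str, SmaFit]:
    """SMA of period-mean Rs vs same-day GPP, one fit per period.

    ``daily`` carries ``diel_date, day_mean_rs, night_mean_rs``; ``gpp_daily``
    carries ``date, gpp`` (g C m-2 day-1).
    """
    d = daily.copy()
    d["date"] = pd.to_datetime(d["diel_date"])
    g = gpp_daily.copy()
    g["date"] = pd.to_datetime(g["date"])
    merged = d.merge(g[["date", "gpp"]], on="date", how="inner").dropna(
        subset=["gpp", "day_mean_rs", "night_mean_rs"])
    return {
        "day": sma_fit(merged["gpp"], merged["day_mean_rs"]),
        "night": sma_fit(merged["gpp"], merged["night_mean_rs"]),
    }
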