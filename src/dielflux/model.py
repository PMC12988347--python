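"""Per-site diel analysis as a fitted-model object.

:class:`DielSiteModel` bundles the full per-site chain — solar day/night
labelling, season selection, the QC cascade, paired diel t-tests, day and
night exponential temperature-response fits, adjustment to the site mean
temperature, and the nighttime-extrapolation bias — behind a statsmodels-like
``Model.fit() -> Results`` interface::

    model = DielSiteModel(hourly_df, meta)          # or .from_csv(...)
    res = model.fit(season="summer")
    print(res.summary())
    res.diel_rs.delta, res.fit_night.q10, res.bias_rs.bias_pct
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diel, qc, solar
from .bias import BiasReport, bias_test, predict_night_from_day
from .diel import DielSummary, TempResponseFit
from .io import SiteMeta, aggregate_hourly, read_flux_table
from .qc import QcReport

__all__ = ["DielSiteModel", "DielSiteResults"]


@dataclass
class DielSiteResults:
    """Estimates and diagnostics of one site-season diel analysis."""

    site_id: str
    season: str
    qc_report: QcReport
    daily: pd.DataFrame                      # paired day/night daily means
    diel_rs: DielSummary
    diel_ts: DielSummary
    diel_swc: DielSummary | None
    fit_day: TempResponseFit
    fit_night: TempResponseFit
    site_mean_ts: float
    adjusted: pd.DataFrame                   # daily + day_rs_adj/night_rs_adj
    diel_rs_adj: DielSummary                 # t-test on adjusted fluxes
    bias_rs: BiasReport
    mean_night_hours: float                  # astronomical, for extrapolation

    @property
    def q10_day(self) -> float:
        return self.fit_day.q10

    @property
    def q10_night(self) -> float:
        return self.fit_night.q10

    def summary(self) -> str:
        r = self
        lines = [
            f"Diel soil-respiration analysis — site {r.site_id} ({r.season})",
            "=" * 64,
            f"days analysed: {r.diel_rs.n_days}   hours: day {r.fit_day.n_hours}, "
            f"night {r.fit_night.n_hours}   site mean Ts: {r.site_mean_ts:.2f} C",
            "-" * 64,
            "delta Rs (night - day): "
            f"{r.diel_rs.delta:+.3f} ± {r.diel_rs.sem:.3f} umol m-2 s-1 "
            f"({r.diel_rs.percent_delta:+.2f}%)  p={r.diel_rs.p_value:.3g} "
            f"[{r.diel_rs.significance}]",
            f"delta Ts (night - day): {r.diel_ts.delta:+.3f} ± {r.diel_ts.sem:.3f} C"
            f"  p={r.diel_ts.p_value:.3g}",
            "-" * 64,
            "temperature response  Rs = Rs0 exp(beta Ts):",
            f"  day   Rs0={r.fit_day.rs0:.3f}  beta={r.fit_day.beta:.4f}"
            f"  Q10={r.q10_day:.3f}  R2={r.fit_day.r2:.3f}",
            f"  night Rs0={r.fit_night.rs0:.3f}  beta={r.fit_night.beta:.4f}"
            f"  Q10={r.q10_night:.3f}  R2={r.fit_night.r2:.3f}",
            "adjusted to site mean Ts: delta Rs_adj "
            f"{r.diel_rs_adj.delta:+.3f} umol m-2 s-1  p={r.diel_rs_adj.p_value:.3g}",
            "-" * 64,
            "night flux from daytime fit: "
            f"pred {r.bias_rs.pred_night_mean:.3f} vs obs {r.bias_rs.obs_night_mean:.3f}"
            f" -> bias {r.bias_rs.bias_pct:+.2f}%  p={r.bias_rs.p_value:.3g}",
        ]
        return "\n".join(lines)

    def to_row(self) -> dict:
        """Flat record for cross-site tables."""
        return {
            "site_id": self.site_id, "season": self.season,
            "n_days": self.diel_rs.n_days,
            "delta_rs": self.diel_rs.delta, "delta_rs_sem": self.diel_rs.sem,
            "percent_delta_rs": self.diel_rs.percent_delta,
            "delta_rs_p": self.diel_rs.p_value,
            "significance": self.diel_rs.significance,
            "delta_ts": self.diel_ts.delta,
            "day_mean_rs": float(self.daily["day_mean_rs"].mean()),
            "night_mean_rs": float(self.daily["night_mean_rs"].mean()),
            "q10_day": self.q10_day, "q10_night": self.q10_night,
            "rs0_day": self.fit_day.rs0, "rs0_night": self.fit_night.rs0,
            "site_mean_ts": self.site_mean_ts,
            "bias_pct": self.bias_rs.bias_pct, "bias_p": self.bias_rs.p_value,
            "flux_gap": self.bias_rs.flux_gap,
            "mean_night_hours": self.mean_night_hours,
        }


class DielSiteModel:
    """Diel day/night analysis of one site's hourly flux record.

    Parameters
    ----------
    series : DataFrame
        Hourly ``timestamp, rs, ts[, swc, treatment, ...]`` in site standard
        time (sub-hourly input is averaged to hours first).
    meta : SiteMeta
        Location, UTC offset and forest class; drives the solar split.
    """

    def __init__(self, series: pd.DataFrame, meta: SiteMeta):
        if "n_subhourly" not in series.columns:
            series = aggregate_hourly(series)
        self.series = series
        self.meta = meta

    @classmethod
    def from_csv(cls, flux_path, meta: SiteMeta,
                 target_depth_cm: float = 5.0) -> "DielSiteModel":
        raw = read_flux_table(flux_path, meta, target_depth_cm=target_depth_cm)
        return cls(aggregate_hourly(raw), meta)

    from_dataframe = __init__  # alias documented for statsmodels parity

    def fit(self, season: str = "summer", *, paired: bool = True,
            fit_method: str = "log_ols",
            min_fit_hours: int = diel.MIN_FIT_HOURS) -> DielSiteResults:
        """Run the full per-site chain and return a results object.

        Raises ``QcError``/``FitError`` when the record cannot support the
        analysis (too few valid values, hours, or paired days); callers
        running many sites catch these and record the exclusion reason.
        """
        labeled = solar.label_hours(self.series, self.meta)
        seasonal = solar.season_filter(labeled, self.meta, season)
        clean, report = qc.apply_qc(seasonal)
        if clean.empty:
            raise qc.QcError("no data left after QC")

        daily = diel.daily_means(clean)
        sid = self.meta.site_id
        diel_rs = diel.diel_test(daily, "rs", site_id=sid, paired=paired)
        diel_ts = diel.diel_test(daily, "ts", site_id=sid, paired=paired)
        diel_swc = (diel.diel_test(daily, "swc", site_id=sid, paired=paired)
                    if daily.get("day_mean_swc") is not None
                    and daily["day_mean_swc"].notna().any() else None)

        fit_day = diel.fit_temp_response(clean, "day", site_id=sid,
                                         method=fit_method,
                                         min_hours=min_fit_hours)
        fit_night = diel.fit_temp_response(clean, "night", site_id=sid,
                                           method=fit_method,
                                           min_hours=min_fit_hours)
        site_mean_ts = float(pd.to_numeric(clean["ts"], errors="coerce").mean())
        adjusted = diel.adjust_to_mean_temp(daily, fit_day, fit_night, site_mean_ts)
        adj_daily = adjusted.rename(columns={"day_rs_adj": "day_mean_rs_adj",
                                             "night_rs_adj": "night_mean_rs_adj"})
        diel_rs_adj = diel.diel_test(adj_daily, "rs_adj", site_id=sid, paired=paired)

        po = predict_night_from_day(clean, fit_day)
        bias_rs = bias_test(po["pred"], po["obs"], site_id=sid)

        night_len = [24.0 - solar.day_length_hours(self.meta.lat, d)
                     for d in pd.to_datetime(
                         pd.unique(clean["diel_date"])).date]
        return DielSiteResults(
            site_id=sid, season=season, qc_report=report, daily=daily,
            diel_rs=diel_rs, diel_ts=diel_ts, diel_swc=diel_swc,
            fit_day=fit_day, fit_night=fit_night, site_mean_ts=site_mean_ts,
            adjusted=adjusted, diel_rs_adj=diel_rs_adj, bias_rs=bias_rs,
            mean_night_hours=float(np.mean(night_len)))
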