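"""Diel-fidelity evaluation of hourly land-model output tables.

Land-surface models are judged on the same day/night contrast as the
observations, but the split follows the models' own radiation forcing: an
hour is night when simulated GPP is (numerically) zero. Summaries are
multi-year day/night means of Rs, Rroot and Rh and the percent by which the
night mean falls short of the day mean; cross-site comparisons reuse the SMA
utilities. Nutrient-competition variants (e.g. ECA-like with no nighttime
root growth vs RD-like with deficit-funded night growth) enter purely as
labels on input tables — nothing here re-implements them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import SmaFit, sma_fit

__all__ = ["GPP_ZERO_EPS", "ModelDielSummary", "gpp_day_night_split",
           "model_diel_summary", "model_sma"]

#: tolerance replacing a literal "GPP == 0" against floating-point storage
GPP_ZERO_EPS = 1e-6  # umol m-2 s-1

TARGETS = ("rs", "rroot", "rh")


@dataclass(frozen=True)
class ModelDielSummary:
    site_id: str
    config_label: str
    day_mean: dict
    night_mean: dict
    pct_night_lower: dict        # 100 * (day - night) / day per target
    n_hours: int
    years: tuple = ()


def gpp_day_night_split(series: pd.DataFrame,
                        eps: float = GPP_ZERO_EPS) -> pd.DataFrame:
    """Label hours day/night from the model's own GPP: night iff gpp <= eps."""
    if "gpp" not in series.columns:
        raise ValueError("model series has no gpp column")
    out = series.copy()
    gpp = pd.to_numeric(out["gpp"], errors="coerce")
    out["period"] = np.where(gpp <= eps, "night", "day")
    return out


def model_diel_summary(labeled: pd.DataFrame, *, site_id: str = "",
                       config_label: str = "",
                       targets=TARGETS) -> ModelDielSummary:
    """Day/night means per target over the full period handed in."""
    targets = [t for t in targets if t in labeled.columns]
    day_mean, night_mean, pct = {}, {}, {}
    for t in targets:
        v = pd.to_numeric(labeled[t], errors="coerce")
        d = float(v[labeled["period"] == "day"].mean())
        n = float(v[labeled["period"] == "night"].mean())
        day_mean[t], night_mean[t] = d, n
        pct[t] = 100.0 * (d - n) / d if d != 0 else np.nan
    years = tuple(sorted(pd.to_datetime(labeled["timestamp"]).dt.year.unique())
                  ) if "timestamp" in labeled.columns else ()
    return ModelDielSummary(site_id, config_label, day_mean, night_mean, pct,
                            n_hours=len(labeled), years=years)


def model_sma(summaries: list[ModelDielSummary], target: str = "rs") -> SmaFit:
    """Cross-site SMA of simulated night vs day means for one target."""
    if len(summaries) < 3:
        raise ValueError(f"need >= 3 sites for SMA, got {len(summaries)}")
    x = [s.day_mean[target] for s in summaries]
    y = [s.night_mean[target] for s in summaries]
    return sma_fit(x, y)
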