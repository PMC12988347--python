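"""Quality-control cascade for hourly, day/night-labelled flux series.

Rules are applied in a fixed order and each removal is accounted for:

1. drop rows from manipulation treatments (warming, drought, ...);
2. drop non-positive Rs, then Rs outside the Tukey fences
   [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of the analysed subset (quantiles by linear
   interpolation);
3. keep only diel dates with at least 3 valid daytime AND 3 valid nighttime
   hours (an hour is valid when both Rs and Ts are finite);
4. keep only calendar months retaining at least 10 such days.

The cascade is idempotent: re-running it on its own output removes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QcError", "QcReport", "drop_treatments", "tukey_fences",
           "drop_nonpositive_and_outliers", "enforce_daily_coverage",
           "enforce_monthly_coverage", "apply_qc"]

CONTROL_LABELS = frozenset({"none", "control", "ambient", ""})

MIN_HOURS_PER_PERIOD = 3
MIN_DAYS_PER_MONTH = 10


class QcError(ValueError):
    """Series fails a QC precondition and the site must be excluded."""


@dataclass
class QcReport:
    initial_rows: int = 0
    removed_treatment: int = 0
    removed_nonpositive: int = 0
    removed_outlier: int = 0
    removed_daily_coverage: int = 0
    removed_monthly_coverage: int = 0
    final_rows: int = 0
    passed: bool = True
    reason: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def drop_treatments(series: pd.DataFrame) -> pd.DataFrame:
    """Keep only control/ambient rows; a missing treatment column keeps all."""
    if "treatment" not in series.columns:
        return series.copy()
    lab = series["treatment"].fillna("none").astype(str).str.strip().str.lower()
    return series.loc[lab.isin(CONTROL_LABELS)].copy()


def tukey_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """[Q1 - k*IQR, Q3 + k*IQR] with linearly interpolated quantiles."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    q1, q3 = np.quantile(v, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def drop_nonpositive_and_outliers(series: pd.DataFrame,
                                  report: QcReport | None = None) -> pd.DataFrame:
    """Remove Rs <= 0, then Rs outside the Tukey fences of what remains.

    Fences are computed on the subset handed in (per site and season), so a
    wet-season tail never widens a dry-season fence. Fewer than 4 finite Rs
    values raise :class:`QcError`.
    """
    rs = pd.to_numeric(series["rs"], errors="coerce")
    finite = rs.notna() & np.isfinite(rs)
    positive = finite & (rs > 0)
    n_nonpos = int((finite & ~ (rs > 0)).sum() + (~finite).sum())
    kept = series.loc[positive]
    if len(kept) < 4:
        raise QcError(f"fewer than 4 positive finite Rs values ({len(kept)})")
    lo, hi = tukey_fences(kept["rs"].to_numpy())
    inside = (kept["rs"] >= lo) & (kept["rs"] <= hi)
    if report is not None:
        report.removed_nonpositive += n_nonpos
        report.removed_outlier += int((~inside).sum())
    return kept.loc[inside].copy()


def _valid_hours(series: pd.DataFrame) -> pd.Series:
    return (pd.to_numeric(series["rs"], errors="coerce").notna()
            & pd.to_numeric(series["ts"], errors="coerce").notna())


def enforce_daily_coverage(series: pd.DataFrame,
                           min_hours: int = MIN_HOURS_PER_PERIOD) -> pd.DataFrame:
    """Keep diel dates with >= ``min_hours`` valid hours in BOTH periods."""
    if series.empty:
        return series.copy()
    valid = series.loc[_valid_hours(series)]
    counts = valid.groupby(["diel_date", "period"], observed=True).size().unstack(
        "period", fill_value=0)
    for col in ("day", "night"):
        if col not in counts.columns:
            counts[col] = 0
    ok_dates = counts.index[(counts["day"] >= min_hours) & (counts["night"] >= min_hours)]
    return series.loc[series["diel_date"].isin(set(ok_dates))].copy()


def enforce_monthly_coverage(series: pd.DataFrame,
                             min_days: int = MIN_DAYS_PER_MONTH) -> pd.DataFrame:
    """Keep calendar months (of diel_date) with >= ``min_days`` surviving days."""
    if series.empty:
        return series.copy()
    dd = pd.to_datetime(series["diel_date"])
    month = dd.dt.to_period("M")
    days_per_month = series.assign(_m=month).groupby("_m")["diel_date"].nunique()
    ok = set(days_per_month.index[days_per_month >= min_days])
    return series.loc[month.isin(ok)].drop(columns=[], errors="ignore").copy()


def apply_qc(series: pd.DataFrame, *, min_hours: int = MIN_HOURS_PER_PERIOD,
             min_days: int = MIN_DAYS_PER_MONTH) -> tuple[pd.DataFrame, QcReport]:
    """Run the full cascade in order and account for every removal."""
    report = QcReport(initial_rows=len(series))
    try:
        s = drop_treatments(series)
        report.removed_treatment = report.initial_rows - len(s)
        s = drop_nonpositive_and_outliers(s, report)
        before = len(s)
        s = enforce_daily_coverage(s, min_hours)
        report.removed_daily_coverage = before - len(s)
        before = len(s)
        s = enforce_monthly_coverage(s, min_days)
        report.removed_monthly_coverage = before - len(s)
        report.final_rows = len(s)
        if s.empty:
            report.passed = False
            report.reason = "no data left after coverage rules"
        return s, report
    except QcError as exc:
        report.passed = False
        report.reason = str(exc)
        report.final_rows = 0
        raise
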