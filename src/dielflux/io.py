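"""Readers/writers for chamber-flux, metadata, GPP and land-model CSV tables.

The ingestion contract is a plain-CSV export convention (no native parsing of
the upstream R-package binary formats):

* flux CSV: ``timestamp_iso, port, rs_umol_m2_s, ts_C_<d>cm, swc_pct_<d>cm,
  treatment`` (one or more depth columns per variable);
* optional partition CSV adds ``rh_umol_m2_s``;
* daily GPP CSV: ``date, gpp_gC_m2_d``;
* hourly model-output CSV: ``timestamp_iso, rs, rroot, rh, gpp, ts_10cm``;
* site metadata YAML: ``site_id, lat, lon, utc_offset, igbp``.

All fluxes are umol CO2 m-2 s-1, temperatures degC, SWC volumetric %.
Timestamps are interpreted in site standard time (no DST); UTC inputs must be
converted by the caller using ``utc_offset``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IGBP_CLASSES",
    "SiteMeta",
    "SchemaError",
    "read_site_meta",
    "write_site_meta",
    "read_flux_table",
    "select_depth",
    "aggregate_hourly",
    "read_model_output",
    "read_gpp_table",
]

#: the five forest land-cover classes handled by the pipeline
IGBP_CLASSES = ("DBF", "EBF", "DNF", "ENF", "MF")


class SchemaError(ValueError):
    """Input table does not match the documented CSV schema."""


@dataclass(frozen=True)
class SiteMeta:
    site_id: str
    lat: float
    lon: float
    utc_offset: float
    igbp: str = "MF"

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of [-90, 90]")
        if self.igbp not in IGBP_CLASSES:
            raise ValueError(f"igbp must be one of {IGBP_CLASSES}, got {self.igbp!r}")

    @property
    def hemisphere(self) -> str:
        return "N" if self.lat >= 0 else "S"


def read_site_meta(path) -> SiteMeta:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return SiteMeta(site_id=str(d["site_id"]), lat=float(d["lat"]), lon=float(d["lon"]),
                    utc_offset=float(d["utc_offset"]), igbp=str(d["igbp"]))


def write_site_meta(meta: SiteMeta, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"site_id": meta.site_id, "lat": meta.lat, "lon": meta.lon,
                        "utc_offset": meta.utc_offset, "igbp": meta.igbp}, fh)


_DEPTH_RE = {
    "ts": re.compile(r"^ts_C_(\d+(?:\.\d+)?)cm$"),
    "swc": re.compile(r"^swc_pct_(\d+(?:\.\d+)?)cm$"),
}


def _depth_columns(columns, var: str) -> dict[float, str]:
    rx = _DEPTH_RE[var]
    out = {}
    for c in columns:
        m = rx.match(c)
        if m:
            out[float(m.group(1))] = c
    return out


def select_depth(records: pd.DataFrame, var: str = "ts",
                 target_cm: float = 5.0) -> tuple[pd.Series, float]:
    """Pick the measurement depth nearest ``target_cm`` (ties -> shallower).

    Returns the chosen column as a Series plus the depth it came from.
    """
    depths = _depth_columns(records.columns, var)
    if not depths:
        raise SchemaError(f"no {var} depth columns found in {list(records.columns)}")
    chosen = min(sorted(depths), key=lambda d: (abs(d - target_cm), d))
    return records[depths[chosen]], chosen


def read_flux_table(path, meta: SiteMeta | None = None, *,
                    target_depth_cm: float = 5.0) -> pd.DataFrame:
    """Read a sub-hourly chamber flux CSV into the working schema.

    Output columns: ``timestamp, port, rs, ts, swc, treatment`` plus
    ``depth_used_ts``/``depth_used_swc`` recorded in ``DataFrame.attrs`` and
    any unrecognised input columns preserved as extras (e.g. ``rh_umol_m2_s``
    becomes ``rh``). Rows are sorted by timestamp (then port).
    """
    raw = pd.read_csv(path)
    required = ["timestamp_iso", "rs_umol_m2_s"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    ts_depths = _depth_columns(raw.columns, "ts")
    if not ts_depths:
        raise SchemaError(f"{path}: no soil-temperature column (ts_C_<depth>cm)")

    out = pd.DataFrame({
        "timestamp": pd.to_datetime(raw["timestamp_iso"]),
        "rs": pd.to_numeric(raw["rs_umol_m2_s"], errors="coerce"),
    })
    out["port"] = raw["port"] if "port" in raw.columns else 1
    out["treatment"] = raw["treatment"] if "treatment" in raw.columns else "none"

    ts_col, ts_depth = select_depth(raw, "ts", target_depth_cm)
    out["ts"] = pd.to_numeric(ts_col, errors="coerce")
    swc_depths = _depth_columns(raw.columns, "swc")
    if swc_depths:
        swc_col, swc_depth = select_depth(raw, "swc", target_depth_cm)
        out["swc"] = pd.to_numeric(swc_col, errors="coerce")
    else:
        out["swc"] = np.nan
        swc_depth = np.nan

    known = set(required + ["port", "treatment"]) | set(ts_depths.values()) \
        | set(swc_depths.values())
    for c in raw.columns:
        if c not in known:
            name = "rh" if c == "rh_umol_m2_s" else c
            out[name] = raw[c]

    out = out.sort_values(["timestamp", "port"], kind="mergesort").reset_index(drop=True)
    out.attrs["depth_used_ts"] = ts_depth
    out.attrs["depth_used_swc"] = swc_depth
    if meta is not None:
        out.attrs["site_id"] = meta.site_id
    return out


def aggregate_hourly(records: pd.DataFrame) -> pd.DataFrame:
    """Average sub-hourly records to the hourly scale.

    Hour bins are left-closed ``[h, h+1)``. Where several chambers/ports
    report in the same hour, each port is averaged first and ports then get
    equal weight. ``n_subhourly`` counts the raw records behind each hour.
    Hours with no records are absent, never filled.
    """
    if records.empty:
        out = records.copy()
        out["n_subhourly"] = pd.Series(dtype=int)
        return out
    df = records.copy()
    df["hour"] = pd.to_datetime(df["timestamp"]).dt.floor("h")
    num_cols = [c for c in ("rs", "ts", "swc", "rh") if c in df.columns]
    if "port" not in df.columns:
        df["port"] = 1
    per_port = df.groupby(["hour", "port"], sort=True)[num_cols].mean()
    hourly = per_port.groupby(level="hour").mean()
    counts = df.groupby("hour")["rs"].size()
    out = hourly.reset_index().rename(columns={"hour": "timestamp"})
    out["n_subhourly"] = counts.to_numpy()
    if "treatment" in df.columns:
        treat = df.groupby("hour")["treatment"].agg(
            lambda s: s.mode().iloc[0] if len(s.mode()) else "none")
        out["treatment"] = treat.to_numpy()
    out.attrs = dict(records.attrs)
    return out


def read_model_output(path, meta: SiteMeta | None = None,
                      tol: float = 0.05) -> pd.DataFrame:
    """Read an hourly land-model output CSV (rs, rroot, rh, gpp, ts).

    Flags (but keeps) hours where ``rs`` differs from ``rroot + rh`` by more
    than ``tol`` relative, adding a boolean ``component_mismatch`` column and
    emitting one warning per file.
    """
    raw = pd.read_csv(path)
    if raw.empty:
        return pd.DataFrame(columns=["timestamp", "rs", "rroot", "rh", "gpp", "ts",
                                     "component_mismatch"])
    required = ["timestamp_iso", "rs", "rroot", "rh", "gpp"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    # model tables write soil temperature as ts_<depth>cm
    model_rx = re.compile(r"^ts_(?:C_)?(\d+(?:\.\d+)?)cm$")
    ts_cols = {float(m.group(1)): c for c in raw.columns
               if (m := model_rx.match(c))}
    if not ts_cols:
        raise SchemaError(f"{path}: no soil-temperature column (ts_<depth>cm)")
    depth = min(sorted(ts_cols), key=lambda d: (abs(d - 10.0), d))
    out = pd.DataFrame({
        "timestamp": pd.to_datetime(raw["timestamp_iso"]),
        "rs": pd.to_numeric(raw["rs"], errors="coerce"),
        "rroot": pd.to_numeric(raw["rroot"], errors="coerce"),
        "rh": pd.to_numeric(raw["rh"], errors="coerce"),
        "gpp": pd.to_numeric(raw["gpp"], errors="coerce"),
        "ts": pd.to_numeric(raw[ts_cols[depth]], errors="coerce"),
    }).sort_values("timestamp").reset_index(drop=True)
    denom = out["rs"].abs().clip(lower=1e-12)
    out["component_mismatch"] = (out["rs"] - (out["rroot"] + out["rh"])).abs() / denom > tol
    if out["component_mismatch"].any():
        warnings.warn(
            f"{path}: rs != rroot + rh beyond {tol:.0%} on "
            f"{int(out['component_mismatch'].sum())} hours", stacklevel=2)
    out.attrs["depth_used_ts"] = depth
    if meta is not None:
        out.attrs["site_id"] = meta.site_id
    return out


def read_gpp_table(path) -> pd.DataFrame:
    """Read a daily GPP CSV (``date, gpp_gC_m2_d``)."""
    raw = pd.read_csv(path)
    missing = [c for c in ("date", "gpp_gC_m2_d") if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame({
        "date": pd.to_datetime(raw["date"]).dt.date,
        "gpp": pd.to_numeric(raw["gpp_gC_m2_d"], errors="coerce"),
    })
    return out.sort_values("date").reset_index(drop=True)
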