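"""Percentile-based extreme-weather indicators from daily records.

A multi-year baseline per region defines a climatology: the 10th and 90th
empirical percentiles of daily mean temperature, the 90th percentile of
precipitation on wet days (precip > 0), and calendar-month means.  Each
region-day is then flagged

* ``extreme_hot``  — daily mean temperature strictly above the 90th percentile,
* ``extreme_cold`` — strictly below the 10th percentile,
* ``extreme_wet``  — precipitation strictly above the wet-day 90th percentile,

and carries two continuous anomalies, ``temp_change`` and ``precip_change``,
relative to the region's baseline calendar-month means, plus a meteorological
season (Mar-May spring, Jun-Aug summer, Sep-Nov autumn, Dec-Feb winter).

Relative (percentile) thresholds adapt to each location's climate: by
construction about 10% of baseline days fall in each extreme temperature
class.  Percentiles use linear interpolation between order statistics; ties
at a threshold fall in the non-extreme class.  Thresholds may be computed
from the whole-year baseline distribution (default) or stratified by
calendar month (``window="month"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Climatology",
    "RegionClimatology",
    "ClimatologyError",
    "SEASON_BY_MONTH",
    "read_weather_table",
    "build_climatology",
    "compute_indicators",
    "season_of",
]

#: Missing-value sentinels common in daily-summary exports.
MISSING_SENTINELS = (9999.9, 999.9, 99.99, -9999.0)

SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


class ClimatologyError(ValueError):
    """Raised when a baseline is too short or a region is uncovered."""


@dataclass
class RegionClimatology:
    """Baseline summaries for one region.

    ``temp_p10``/``temp_p90`` are scalars in whole-year mode and month-keyed
    mappings in monthly mode.  ``precip_p90_wet`` is NaN when the baseline
    has no wet days (the extreme-wet flag is then always 0).
    """

    temp_p10: float | dict[int, float]
    temp_p90: float | dict[int, float]
    precip_p90_wet: float
    monthly_mean_temp: dict[int, float]
    monthly_mean_precip: dict[int, float]
    n_baseline_days: int

    def thresholds(self, month: int) -> tuple[float, float]:
        if isinstance(self.temp_p10, dict):
            return self.temp_p10[month], self.temp_p90[month]
        return self.temp_p10, self.temp_p90


@dataclass
class Climatology:
    regions: dict[str, RegionClimatology]
    baseline_start: pd.Timestamp
    baseline_end: pd.Timestamp
    window: str = "year"
    notes: list[str] = field(default_factory=list)


def read_weather_table(path, sentinels=MISSING_SENTINELS) -> pd.DataFrame:
    """Read a delimited daily-summary file (region, date, tmean[, tmax], precip).

    Values matching common missing-data sentinels (e.g. 9999.9) are mapped to
    missing.
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    df["date"] = pd.to_datetime(df["date"])
    for col in ("tmean", "tmax", "precip"):
        if col in df.columns:
            df[col] = df[col].replace(list(sentinels), np.nan)
    return df


def season_of(date) -> str:
    return SEASON_BY_MONTH[pd.Timestamp(date).month]


def build_climatology(
    weather: pd.DataFrame,
    baseline_start,
    baseline_end,
    window: str = "year",
) -> Climatology:
    """Compute per-region percentile thresholds and monthly means.

    Requires at least 365 observed days per region inside the baseline;
    regions below that are rejected by name.  Percentiles use the
    linear-interpolation convention.
    """
    if window not in ("year", "month"):
        raise ValueError(f"window must be 'year' or 'month', got {window!r}")
    start, end = pd.Timestamp(baseline_start), pd.Timestamp(baseline_end)
    if end < start:
        raise ClimatologyError("baseline end precedes baseline start")
    dates = pd.to_datetime(weather["date"])
    base = weather.loc[(dates >= start) & (dates <= end)].copy()
    base["date"] = pd.to_datetime(base["date"])
    regions: dict[str, RegionClimatology] = {}
    notes: list[str] = []
    for region, grp in base.groupby("region", sort=True):
        tm = grp["tmean"].dropna()
        if len(tm) < 365:
            raise ClimatologyError(
                f"region {region!r} has only {len(tm)} baseline days (< 365)"
            )
        months = grp["date"].dt.month
        if window == "year":
            p10 = float(np.percentile(tm, 10))
            p90 = float(np.percentile(tm, 90))
        else:
            p10 = {
                int(m): float(np.percentile(grp.loc[months == m, "tmean"].dropna(), 10))
                for m in range(1, 13)
            }
            p90 = {
                int(m): float(np.percentile(grp.loc[months == m, "tmean"].dropna(), 90))
                for m in range(1, 13)
            }
        wet = grp.loc[grp["precip"] > 0, "precip"].dropna()
        if len(wet):
            p90_wet = float(np.percentile(wet, 90))
        else:
            p90_wet = float("nan")
            notes.append(f"region {region!r}: no wet baseline days; extreme_wet always 0")
        mmt = grp.groupby(months)["tmean"].mean()
        mmp = grp.groupby(months)["precip"].mean()
        if set(mmt.index) != set(range(1, 13)):
            missing = sorted(set(range(1, 13)) - set(mmt.index))
            raise ClimatologyError(
                f"region {region!r}: no baseline data for months {missing}"
            )
        regions[str(region)] = RegionClimatology(
            temp_p10=p10,
            temp_p90=p90,
            precip_p90_wet=p90_wet,
            monthly_mean_temp={int(m): float(v) for m, v in mmt.items()},
            monthly_mean_precip={int(m): float(v) for m, v in mmp.items()},
            n_baseline_days=int(len(tm)),
        )
    return Climatology(regions, start, end, window=window, notes=notes)


def compute_indicators(weather: pd.DataFrame, clim: Climatology) -> pd.DataFrame:
    """Derive the indicator table for every region-day in ``weather``.

    Extreme flags use strict inequalities, so a day exactly at a threshold is
    not extreme, and hot and cold can never both be set.  Rows with missing
    mean temperature get missing indicators and are counted in the
    climatology's notes.
    """
    missing_regions = sorted(set(weather["region"].astype(str)) - set(clim.regions))
    if missing_regions:
        raise ClimatologyError(f"no climatology for regions {missing_regions}")
    df = weather.copy()
    df["date"] = pd.to_datetime(df["date"])
    month = df["date"].dt.month
    rows = {
        "extreme_hot": np.full(len(df), np.nan),
        "extreme_cold": np.full(len(df), np.nan),
        "extreme_wet": np.zeros(len(df)),
        "temp_change": np.full(len(df), np.nan),
        "precip_change": np.full(len(df), np.nan),
    }
    tmean = df["tmean"].to_numpy(float)
    precip = df["precip"].to_numpy(float)
    regions = df["region"].astype(str).to_numpy()
    months = month.to_numpy()
    n_missing = 0
    for i in range(len(df)):
        rc = clim.regions[regions[i]]
        p10, p90 = rc.thresholds(int(months[i]))
        if np.isnan(tmean[i]):
            n_missing += 1
        else:
            rows["extreme_hot"][i] = float(tmean[i] > p90)
            rows["extreme_cold"][i] = float(tmean[i] < p10)
            rows["temp_change"][i] = tmean[i] - rc.monthly_mean_temp[int(months[i])]
        if not np.isnan(precip[i]):
            rows["extreme_wet"][i] = float(
                not np.isnan(rc.precip_p90_wet) and precip[i] > rc.precip_p90_wet
            )
            rows["precip_change"][i] = precip[i] - rc.monthly_mean_precip[int(months[i])]
    out = pd.DataFrame(
        {
            "region": regions,
            "date": df["date"].to_numpy(),
            "tmean": tmean,
            "precip": precip,
            **rows,
            "season": month.map(SEASON_BY_MONTH).to_numpy(),
        }
    )
    if n_missing:
        clim.notes.append(f"{n_missing} rows with missing tmean -> missing indicators")
    return out
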