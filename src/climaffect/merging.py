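"""Region-day join of scored posts, weather indicators, and vulnerability.

The analysis table has one row per post that found both a weather record for
its (region, date) and a vulnerability record for its region.  Joins are
inner with explicit drop accounting — no imputation — and the row
conservation identity matched + dropped == input is asserted every run.

Vulnerability indices (population density, exposure, sensitivity,
adaptability) are dichotomized at the cross-region median with a strict
inequality: a region is "high" only if its value exceeds the median, so the
median region itself is "low".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["MergeReport", "MergeError", "VULNERABILITY_INDICES", "dichotomize", "merge_analysis"]

VULNERABILITY_INDICES = ("population_density", "exposure", "sensitivity", "adaptability")


class MergeError(ValueError):
    pass


@dataclass
class MergeReport:
    n_posts_in: int = 0
    n_matched: int = 0
    n_dropped_no_weather: int = 0
    n_dropped_no_vulnerability: int = 0
    missing_vuln_regions: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_no_weather + self.n_dropped_no_vulnerability


def dichotomize(values: pd.Series) -> pd.Series:
    """High/low split at the median of all regions (strictly greater = high).

    Missing values are excluded from the median and flagged missing in the
    output.  The median of an even count is the mean of the middle two.
    """
    if values.notna().sum() < 2:
        raise MergeError("dichotomize needs at least 2 non-missing regions")
    med = values.median(skipna=True)
    out = values > med
    return out.where(values.notna(), other=pd.NA)


def merge_analysis(
    posts: pd.DataFrame,
    indicators: pd.DataFrame,
    vulnerability: pd.DataFrame,
) -> tuple[pd.DataFrame, MergeReport]:
    """Inner-join posts to (region, date) indicators, then to vulnerability.

    Duplicate (region, date) rows in the indicator table make the join
    ambiguous and are a hard error.  Returns the analysis table and a report
    of drop counts.
    """
    dup = indicators.duplicated(subset=["region", "date"])
    if dup.any():
        bad = indicators.loc[dup, ["region", "date"]].iloc[0]
        raise MergeError(
            f"duplicate (region, date) in indicators, e.g. ({bad['region']}, {bad['date']})"
        )
    report = MergeReport(n_posts_in=len(posts))
    posts = posts.copy()
    posts["date"] = pd.to_datetime(posts["date"])
    ind = indicators.copy()
    ind["date"] = pd.to_datetime(ind["date"])
    ind = ind.rename(columns={"tmean": "wx_tmean", "precip": "wx_precip"})
    step1 = posts.merge(ind, on=["region", "date"], how="inner")
    report.n_dropped_no_weather = len(posts) - len(step1)

    vuln = vulnerability.copy()
    for col in VULNERABILITY_INDICES:
        if col not in vuln.columns:
            raise MergeError(f"vulnerability table missing column {col!r}")
        vuln[f"{col}_high"] = dichotomize(vuln[col]).astype("boolean")
    merged = step1.merge(vuln, on="region", how="inner")
    report.n_dropped_no_vulnerability = len(step1) - len(merged)
    report.missing_vuln_regions = sorted(
        set(step1["region"]) - set(vuln["region"])
    )
    report.n_matched = len(merged)
    assert report.n_matched + report.n_dropped == report.n_posts_in
    return merged, report
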