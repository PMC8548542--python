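"""Telemetry metrics: per-connection rates, censoring, windowed averages.

The 30-minute household telemetry is reduced to four per-region volume
characteristics per analysis period and direction: the pre-dawn minimum
(4:30-5:30 a.m.), the morning daytime average (9 a.m.-noon), the evening
maximum (8:30-10 p.m.), and an overall daytime average over working hours
(9 a.m.-5 p.m.).  All are in bytes per 30 minutes per active connection.
Windows are half-open on the interval start label, so 8:30-10 p.m. covers
the slots starting 20:30, 21:00 and 21:30.

Lockdown changes are reported per region as absolute differences against a
pre-pandemic baseline window and, where the baseline is positive, relative
differences.

Timestamps are treated as local clock time with no daylight-saving
adjustment; the default baseline window spans an Australian DST transition
and slot-of-day arithmetic deliberately follows the wall clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisPeriod",
    "BASELINE",
    "WAVE1",
    "WAVE2",
    "METRIC_WINDOWS",
    "METRIC_COLUMNS",
    "per_connection_rates",
    "censor_timeseries_outliers",
    "period_metrics",
    "compute_changes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisPeriod:
    """A named date window; ``start`` and ``end`` are inclusive.

    ``weekdays_only`` restricts the *daytime* metrics (morning and overall
    daytime averages) to weekdays; the pre-dawn and evening windows always
    use every day, since home presence outside work hours is not a
    school/work-day phenomenon.
    """

    label: str
    start: date
    end: date
    weekdays_only: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.label}: start must be <= end")

    def contains(self, days: pd.Series) -> pd.Series:
        """Membership mask for a series of normalised datetime64 days."""
        return (days >= pd.Timestamp(self.start)) & (days <= pd.Timestamp(self.end))


BASELINE = AnalysisPeriod("baseline", date(2019, 10, 10), date(2019, 11, 29))
WAVE1 = AnalysisPeriod("wave1", date(2020, 4, 18), date(2020, 4, 24))
WAVE2 = AnalysisPeriod("wave2", date(2020, 8, 8), date(2020, 8, 14))

# metric -> (start minute-of-day, end minute-of-day), half-open
METRIC_WINDOWS: dict[str, tuple[int, int]] = {
    "predawn_min": (4 * 60 + 30, 5 * 60 + 30),
    "daytime_avg": (9 * 60, 12 * 60),
    "evening_max": (20 * 60 + 30, 22 * 60),
    "overall_daytime": (9 * 60, 17 * 60),
}
_DAYTIME_METRICS = frozenset({"daytime_avg", "overall_daytime"})
METRIC_COLUMNS = tuple(METRIC_WINDOWS)


def per_connection_rates(obs: pd.DataFrame,
                         min_connections: int = 50
                         ) -> tuple[pd.DataFrame, int]:
    """Normalise volumes to bytes per active connection.

    Rows with fewer than ``min_connections`` active connections (including
    zero) are dropped — the privacy floor of the telemetry provider — and
    the dropped-row count is returned alongside the rates.
    """
    keep = obs["active_connections"] >= max(min_connections, 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d intervals below the %d-connection floor",
                    n_dropped, min_connections)
    kept = obs[keep]
    rates = pd.DataFrame({
        "region_id": kept["region_id"].to_numpy(),
        "interval_start": pd.to_datetime(kept["interval_start"]).to_numpy(),
        "download_rate": (kept["download_bytes"]
                          / kept["active_connections"]).to_numpy(),
        "upload_rate": (kept["upload_bytes"]
                        / kept["active_connections"]).to_numpy(),
    })
    bad_minutes = ~pd.DatetimeIndex(rates["interval_start"]).minute.isin((0, 30))
    if bad_minutes.any():
        raise ValueError(f"{int(bad_minutes.sum())} intervals are not aligned "
                         "to the half-hour grid")
    return rates, n_dropped


def _with_time_columns(rates: pd.DataFrame) -> pd.DataFrame:
    ts = pd.DatetimeIndex(rates["interval_start"])
    return rates.assign(
        _day=ts.normalize(),
        _minute=ts.hour * 60 + ts.minute,
        _weekday=ts.weekday < 5,
    )


def censor_timeseries_outliers(rates: pd.DataFrame,
                               period: AnalysisPeriod | None = None,
                               sd_multiplier: float = 3.0,
                               pooled: bool = False
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove per-slot outliers beyond ``sd_multiplier`` standard deviations.

    Within each region x slot-of-day group (or slot-of-day only when
    ``pooled``) over the period's days, values with |x - mean| > k * SD are
    set to missing in a single, non-iterated pass, separately per direction.
    Such spikes in real telemetry typically reflect network-management or
    infrastructure configuration changes, which are localised — hence the
    per-region default.  Groups with zero SD are left untouched.

    Returns ``(censored, removals)`` where ``removals`` counts censored
    points per region and direction.
    """
    df = _with_time_columns(rates)
    if period is not None:
        df = df[period.contains(df["_day"])]
    df = df.copy()
    keys = ["_minute"] if pooled else ["region_id", "_minute"]
    for col in ("download_rate", "upload_rate"):
        grp = df.groupby(keys, sort=False)[col]
        mean = grp.transform("mean")
        sd = grp.transform("std")
        outlier = (df[col] - mean).abs() > sd_multiplier * sd
        outlier &= sd.notna() & (sd > 0)
        df.loc[outlier, col] = np.nan
    removals = (df[["download_rate", "upload_rate"]].isna()
                .groupby(df["region_id"], sort=True).sum()
                .rename(columns={"download_rate": "download_censored",
                                 "upload_rate": "upload_censored"})
                .reset_index())
    return df.drop(columns=["_day", "_minute", "_weekday"]), removals


def period_metrics(rates: pd.DataFrame, period: AnalysisPeriod) -> pd.DataFrame:
    """Windowed per-connection volume averages for one period.

    Returns one row per region x direction with the four metric columns
    (NaN where a window has no data, e.g. weekday-only metrics on
    weekend-only telemetry) and ``n_intervals``, the number of non-missing
    intervals contributing to the period.
    """
    df = _with_time_columns(rates)
    df = df[period.contains(df["_day"])]
    if df.empty:
        raise ValueError(f"no telemetry falls inside period {period.label!r}")

    frames = []
    for direction, col in (("download", "download_rate"),
                           ("upload", "upload_rate")):
        res = (df.groupby("region_id", sort=True)[col]
               .count().rename("n_intervals").to_frame())
        for metric, (lo, hi) in METRIC_WINDOWS.items():
            mask = (df["_minute"] >= lo) & (df["_minute"] < hi)
            if period.weekdays_only and metric in _DAYTIME_METRICS:
                mask &= df["_weekday"]
            res[metric] = df[mask].groupby("region_id", sort=True)[col].mean()
        res.insert(0, "direction", direction)
        frames.append(res.reset_index())
    out = (pd.concat(frames, ignore_index=True)
           .sort_values(["region_id", "direction"], ignore_index=True))

    ordering_violated = ((out["predawn_min"] > out["daytime_avg"])
                         | (out["daytime_avg"] > out["evening_max"])).fillna(False)
    if ordering_violated.any():
        logger.warning(
            "%d region/direction rows violate predawn <= daytime <= evening",
            int(ordering_violated.sum()))
    out.insert(1, "period", period.label)
    return out


def compute_changes(baseline: pd.DataFrame, wave: pd.DataFrame
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Per-region changes of each metric against the baseline period.

    Absolute change is wave minus baseline (bytes per 30 min per
    connection); relative change divides by the baseline value and is
    missing where the baseline is zero or missing.  Regions present on only
    one side are excluded and listed in the second return value.
    """
    keys = ["region_id", "direction"]
    merged = baseline.merge(wave, on=keys, suffixes=("_base", "_wave"))
    base_regions = set(baseline["region_id"])
    wave_regions = set(wave["region_id"])
    excluded = sorted(base_regions ^ wave_regions)
    if excluded:
        logger.warning("%d regions missing from one side: %s",
                       len(excluded), excluded[:10])

    out = merged[keys].copy()
    out["wave"] = merged["period_wave"]
    for metric in METRIC_WINDOWS:
        b = merged[f"{metric}_base"]
        w = merged[f"{metric}_wave"]
        out[f"{metric}_abs_change"] = w - b
        out[f"{metric}_rel_change"] = np.where(b > 0, (w - b) / b, np.nan)
    return out, excluded
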