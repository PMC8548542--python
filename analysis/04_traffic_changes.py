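"""Reduce telemetry to per-region windowed metrics and lockdown changes.

Normalises volumes to bytes per active connection, censors 3-SD outliers
within region x slot-of-day groups, computes the four windowed volume
characteristics for the baseline and lockdown periods, and writes the
baseline-relative changes.
"""

import sys
from datetime import timedelta
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _scenario import INPUTS, RESULTS, SCENARIO

from homenet.traffic import (
    AnalysisPeriod,
    censor_timeseries_outliers,
    compute_changes,
    per_connection_rates,
    period_metrics,
)


def main() -> None:
    traffic = pd.read_csv(INPUTS / "traffic.csv", dtype={"region_id": str},
                          parse_dates=["interval_start"])
    rates, n_dropped = per_connection_rates(traffic, SCENARIO.min_connections)
    print(f"{len(rates)} intervals kept, {n_dropped} below the "
          f"{SCENARIO.min_connections}-connection floor")

    base = AnalysisPeriod("baseline", SCENARIO.baseline_start,
                          SCENARIO.baseline_start
                          + timedelta(SCENARIO.baseline_days - 1))
    wave = AnalysisPeriod("wave1", SCENARIO.wave_start,
                          SCENARIO.wave_start + timedelta(SCENARIO.wave_days - 1))

    metrics = {}
    for period in (base, wave):
        censored, removals = censor_timeseries_outliers(rates, period)
        n_removed = int(removals[["download_censored",
                                  "upload_censored"]].to_numpy().sum())
        metrics[period.label] = period_metrics(censored, period)
        metrics[period.label].to_csv(
            RESULTS / f"period_metrics_{period.label}.csv", index=False)
        print(f"{period.label}: censored {n_removed} points")

    changes, excluded = compute_changes(metrics["baseline"], metrics["wave1"])
    changes.to_csv(RESULTS / "changes_wave1.csv", index=False)
    up = changes[changes["direction"] == "upload"]
    print(f"wave1 upload daytime change: mean "
          f"{up['daytime_avg_abs_change'].mean():,.0f} bytes/conn/30min "
          f"(relative {up['daytime_avg_rel_change'].mean():.2%})")


if __name__ == "__main__":
    main()
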