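"""End-to-end orchestration: generate/load -> index -> aggregate -> traffic
-> associations, with a manifest and machine-readable summary.

A run is driven by a single :class:`RunConfig`, either wrapping a synthetic
:class:`~homenet.config.ScenarioConfig` or pointing at a directory of input
CSVs with the same schemas the generator writes.  Every intermediate table
is written to the output directory; the manifest records the configuration
hash, the seed and per-stage row counts so each number in the summary can be
traced back to an intermediate file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import occupations as occ_mod
from . import regions as reg_mod
from . import stats as stats_mod
from . import synth
from . import traffic as traffic_mod
from .config import ScenarioConfig
from .traffic import AnalysisPeriod

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "ValidationReport"]

logger = logging.getLogger(__name__)

INPUT_TABLES = {
    "employment_records": ["occupation_code", "contract_type"],
    "occupation_earnings": ["occupation_code", "avg_weekly_earnings"],
    "wfh_crosswalk": ["source_code", "target_code", "wfh_flag"],
    "wfh_overrides": ["occupation_code", "wfh_flag"],
    "region_occupation_counts": ["region_id", "occupation_code", "count"],
    "region_covariates": ["region_id", "prop_families_children"],
    "adjacency": ["region_id", "neighbour_id"],
    "traffic": ["region_id", "interval_start", "download_bytes",
                "upload_bytes", "active_connections"],
    "survey": ["income_group", "changed_work_environment"],
}

_STR_COLS = {"occupation_code", "region_id", "neighbour_id", "source_code",
             "target_code"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``scenario`` (synthetic generation) or ``input_dir``
    (user-supplied CSVs) must be set.  ``periods`` defaults to the study
    windows implied by the scenario, or to the canonical baseline/wave
    windows for user data.
    """

    outdir: str = "results/run"
    scenario: ScenarioConfig | None = None
    input_dir: str | None = None
    periods: tuple[AnalysisPeriod, ...] | None = None
    min_connections: int = 50
    sd_multiplier: float = 3.0
    pooled_censoring: bool = False
    ci_method: str = "normal"
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of `scenario` and `input_dir` must be set")
        if self.input_dir is not None and self.periods is None:
            object.__setattr__(
                self, "periods",
                (traffic_mod.BASELINE, traffic_mod.WAVE1, traffic_mod.WAVE2))

    def resolved_periods(self) -> tuple[AnalysisPeriod, ...]:
        if self.periods is not None:
            return tuple(self.periods)
        sc = self.scenario
        return (
            AnalysisPeriod("baseline", sc.baseline_start,
                           sc.baseline_start + timedelta(sc.baseline_days - 1)),
            AnalysisPeriod("wave1", sc.wave_start,
                           sc.wave_start + timedelta(sc.wave_days - 1)),
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "outdir": self.outdir,
            "input_dir": self.input_dir,
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "periods": None if self.periods is None else [
                {"label": p.label, "start": p.start.isoformat(),
                 "end": p.end.isoformat(), "weekdays_only": p.weekdays_only}
                for p in self.periods],
            "min_connections": self.min_connections,
            "sd_multiplier": self.sd_multiplier,
            "pooled_censoring": self.pooled_censoring,
            "ci_method": self.ci_method,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if d.get("scenario"):
            d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        if d.get("periods"):
            d["periods"] = tuple(
                AnalysisPeriod(p["label"], date.fromisoformat(p["start"]),
                               date.fromisoformat(p["end"]),
                               p.get("weekdays_only", True))
                for p in d["periods"])
        return cls(**{k: v for k, v in d.items() if v is not None
                      or k in ("scenario", "input_dir", "periods")})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# input loading / validation


def _read_inputs(input_dir) -> dict[str, pd.DataFrame]:
    input_dir = Path(input_dir)
    tables = {}
    for name, required in INPUT_TABLES.items():
        path = input_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table: {path}")
        dtypes = {c: str for c in required if c in _STR_COLS}
        tables[name] = pd.read_csv(path, dtype=dtypes)
    return tables


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, message: str) -> None:
        self.violations.append(message)


def validate_inputs(input_dir) -> ValidationReport:
    """Schema, range and referential checks over an input directory.

    Reports every violation with a row reference rather than stopping at
    the first; unreadable or missing files raise immediately.
    """
    tables = _read_inputs(input_dir)
    report = ValidationReport()

    for name, required in INPUT_TABLES.items():
        missing = [c for c in required if c not in tables[name].columns]
        if missing:
            report.add(f"{name}: missing columns {missing}")
    if report.violations:
        return report

    rec = tables["employment_records"]
    bad = ~rec["contract_type"].isin(occ_mod.CONTRACT_TYPES)
    for i in rec.index[bad][:20]:
        report.add(f"employment_records row {i}: unknown contract type "
                   f"{rec.at[i, 'contract_type']!r}")

    earn = tables["occupation_earnings"]
    for i in earn.index[earn["avg_weekly_earnings"] <= 0][:20]:
        report.add(f"occupation_earnings row {i}: non-positive earnings")

    for tname, col in (("wfh_crosswalk", "wfh_flag"),
                       ("wfh_overrides", "wfh_flag")):
        t = tables[tname]
        if len(t):
            for i in t.index[~t[col].isin((0, 1))][:20]:
                report.add(f"{tname} row {i}: {col} not binary")

    counts = tables["region_occupation_counts"]
    for i in counts.index[counts["count"] < 0][:20]:
        report.add(f"region_occupation_counts row {i}: negative count")
    known_codes = set(earn["occupation_code"])
    unknown = ~counts["occupation_code"].isin(known_codes)
    for i in counts.index[unknown][:20]:
        report.add(f"region_occupation_counts row {i}: occupation code "
                   f"{counts.at[i, 'occupation_code']!r} has no earnings entry")

    cov = tables["region_covariates"]
    prop_cols = [c for c in cov.columns if c.startswith("prop_")]
    for col in prop_cols:
        bad = ~cov[col].between(0, 1)
        for i in cov.index[bad][:20]:
            report.add(f"region_covariates row {i}: {col} outside [0, 1]")

    tr = tables["traffic"]
    ts = pd.to_datetime(tr["interval_start"])
    misaligned = ~ts.dt.minute.isin((0, 30))
    for i in tr.index[misaligned][:20]:
        report.add(f"traffic row {i}: interval_start not aligned to the "
                   "half-hour grid")
    for col in ("download_bytes", "upload_bytes", "active_connections"):
        for i in tr.index[tr[col] < 0][:20]:
            report.add(f"traffic row {i}: negative {col}")
    count_regions = set(counts["region_id"])
    foreign = ~tr["region_id"].isin(count_regions)
    if foreign.any():
        report.add(f"traffic: {int(foreign.sum())} rows reference regions "
                   "absent from region_occupation_counts")

    adj = tables["adjacency"]
    if len(adj):
        pairs = set(zip(adj["region_id"], adj["neighbour_id"]))
        asym = [(a, b) for a, b in pairs if (b, a) not in pairs]
        for a, b in asym[:20]:
            report.add(f"adjacency: pair ({a}, {b}) lacks its mirror")
        selfloops = adj["region_id"] == adj["neighbour_id"]
        for i in adj.index[selfloops][:20]:
            report.add(f"adjacency row {i}: region is its own neighbour")
    return report


# ---------------------------------------------------------------------------
# pipeline


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _correlate(df: pd.DataFrame, xcol: str, ycol: str,
               sd_multiplier: float) -> dict[str, Any]:
    res = stats_mod.censored_pearson(df[xcol], df[ycol], sd_multiplier)
    return {"x": xcol, "y": ycol, "rho": res.rho, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "n_used": res.n_used,
            "n_censored": res.n_censored, "defined": res.defined}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and write all artefacts to ``outdir``.

    Stages: generate (synthetic only) -> occupation index -> regional
    aggregation -> traffic metrics per period -> association battery.
    Returns the results summary (also written as ``summary.json``); any
    stage failure raises :class:`StageError` naming the stage, with the
    tables written so far retained in ``outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, int] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        df.to_csv(outdir / f"{name}.csv", index=False)
        written[name] = len(df)

    # -- stage: inputs -----------------------------------------------------
    try:
        if config.scenario is not None:
            tables = synth.write_scenario(config.scenario, outdir / "inputs")
        else:
            tables = _read_inputs(config.input_dir)
        for name, df in tables.items():
            written[f"inputs/{name}"] = len(df)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'inputs' failed: {exc}") from exc

    # -- stage: occupation index ------------------------------------------
    try:
        measures = occ_mod.income_security_index(
            tables["employment_records"], tables["occupation_earnings"])
        wfh, unlinked = occ_mod.propagate_wfh(
            tables["wfh_crosswalk"], tables["wfh_overrides"],
            all_codes=measures["occupation_code"])
        measures = measures.merge(wfh, on="occupation_code", how="left")
        emit("occupation_measures", measures)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'occupation_index' failed: {exc}") from exc

    # -- stage: regional measures -----------------------------------------
    try:
        regional = reg_mod.regional_weighted_averages(
            tables["region_occupation_counts"], measures)
        regional = regional.merge(tables["region_covariates"],
                                  on="region_id", how="left")
        above, median = reg_mod.classify_by_median(
            regional.loc[regional["covered"], "income_security"])
        regional["above_median_security"] = above.reindex(regional.index)
        emit("regional_measures", regional)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'regional_measures' failed: {exc}") from exc

    # -- stage: traffic metrics -------------------------------------------
    try:
        rates, n_dropped = traffic_mod.per_connection_rates(
            tables["traffic"], config.min_connections)
        periods = config.resolved_periods()
        baseline_period = periods[0]
        metrics: dict[str, pd.DataFrame] = {}
        removal_frames = []
        for period in periods:
            censored, removals = traffic_mod.censor_timeseries_outliers(
                rates, period, config.sd_multiplier,
                pooled=config.pooled_censoring)
            metrics[period.label] = traffic_mod.period_metrics(censored, period)
            removal_frames.append(removals.assign(period=period.label))
            emit(f"period_metrics_{period.label}", metrics[period.label])
        emit("censoring_removals", pd.concat(removal_frames, ignore_index=True))
        changes: dict[str, pd.DataFrame] = {}
        for period in periods[1:]:
            change, excluded = traffic_mod.compute_changes(
                metrics[baseline_period.label], metrics[period.label])
            changes[period.label] = change
            emit(f"changes_{period.label}", change)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'traffic_metrics' failed: {exc}") from exc

    # -- stage: associations ----------------------------------------------
    try:
        analysis = regional[regional["covered"]].copy()
        wave_label = periods[1].label if len(periods) > 1 else None
        correlations = [
            _correlate(analysis, "income_security", "wfh_fraction",
                       config.sd_multiplier),
        ]
        if "prop_families_children" in analysis.columns:
            correlations.append(_correlate(
                analysis, "income_security", "prop_families_children",
                config.sd_multiplier))

        base = metrics[baseline_period.label]
        for direction in ("download", "upload"):
            b = base[base["direction"] == direction][
                ["region_id", "daytime_avg"]].rename(
                    columns={"daytime_avg": f"{direction}_baseline_daytime"})
            analysis = analysis.merge(b, on="region_id", how="left")
        if "prop_families_children" in analysis.columns:
            correlations.append(_correlate(
                analysis, "prop_families_children", "download_baseline_daytime",
                config.sd_multiplier))

        pca_input = None
        for label, change in changes.items():
            for direction in ("download", "upload"):
                sub = change[change["direction"] == direction]
                for col in ("daytime_avg_abs_change", "daytime_avg_rel_change"):
                    name = f"{direction}_{col}_{label}"
                    c = sub[["region_id", col]].rename(columns={col: name})
                    analysis = analysis.merge(c, on="region_id", how="left")
                    correlations.append(_correlate(
                        analysis, "income_security", name,
                        config.sd_multiplier))
            pca_col = f"upload_daytime_avg_abs_change_{label}"
            if pca_input is None and pca_col in analysis.columns:
                pca_input = analysis[["income_security",
                                      "prop_families_children", pca_col]]
        emit("analysis_table", analysis)

        summary: dict[str, Any] = {
            "median_income_security": median,
            "correlations": correlations,
            "n_intervals_dropped_below_connection_floor": n_dropped,
        }

        if "city" in analysis.columns and analysis["city"].nunique() == 2:
            cities = sorted(analysis["city"].unique())
            tt = stats_mod.two_sample_t(
                analysis.loc[analysis["city"] == cities[0], "income_security"],
                analysis.loc[analysis["city"] == cities[1], "income_security"])
            summary["city_ttest"] = {"cities": cities, "t": tt.statistic,
                                     "p": tt.pvalue, "df": tt.df}

        table = stats_mod.ContingencyTable.from_survey(tables["survey"])
        fisher = stats_mod.fisher_exact_or(table, ci_method=config.ci_method)
        summary["survey_fisher"] = {
            "table": [table.a, table.b, table.c, table.d],
            "odds_ratio": fisher.odds_ratio, "ci_low": fisher.ci_low,
            "ci_high": fisher.ci_high, "p_two_tailed": fisher.p_two_tailed,
            "degenerate": fisher.degenerate, "ci_method": fisher.ci_method,
        }

        adjacency = tables["adjacency"]
        if len(adjacency):
            moran_vars = {"income_security": analysis.set_index("region_id")[
                "income_security"]}
            if wave_label is not None:
                col = f"upload_daytime_avg_abs_change_{wave_label}"
                moran_vars["upload_daytime_change"] = analysis.set_index(
                    "region_id")[col]
            summary["morans_i"] = {}
            for vname, vals in moran_vars.items():
                mi = stats_mod.morans_i(vals.dropna(), adjacency,
                                        config.n_permutations, config.seed)
                summary["morans_i"][vname] = {
                    "I": mi.I, "expected_I": mi.expected_I,
                    "p_permutation": mi.p_permutation,
                    "n_permutations": mi.n_permutations,
                }

        if pca_input is not None and pca_input.dropna().shape[0] >= 4:
            pca = stats_mod.pca_three_vars(pca_input)
            summary["pca"] = {
                "variables": list(pca.loadings.index),
                "loadings": pca.loadings.round(6).to_dict(orient="list"),
                "variance_explained": [float(v)
                                       for v in pca.variance_explained],
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'association' failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "row_counts": written,
        "periods": [p.label for p in periods],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
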