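"""Scenario and run configuration.

A :class:`ScenarioConfig` fully determines one synthetic study: the number of
areal units and occupations, the traffic windows, and the planted statistical
structure (correlations, lockdown effect size, survey odds ratio).  A fixed
seed makes every generated table byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Any

import yaml

__all__ = ["ScenarioConfig"]


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ValueError(f"{field_name}: {message}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Free parameters of the synthetic scenario generator.

    Parameters
    ----------
    seed
        Seed for all randomness; identical seeds give byte-identical tables.
    n_regions, n_occupations, persons_per_region
        Size of the synthetic study: areal units (SA2-style neighbourhoods),
        4-digit occupation groups, and employed persons per region.
    baseline_days, wave_days
        Length of the pre-lockdown reference window and the lockdown window,
        in days, starting at ``baseline_start`` and ``wave_start``.
    planted_rho_security_wfh
        Target point-biserial correlation between the per-occupation income
        security index and the binary work-from-home flag.
    planted_rho_security_children
        Target correlation between regional income security and the
        proportion of families with children.
    planted_upload_effect
        Lockdown increase of per-connection daytime traffic (bytes per
        30 min per active connection) at the most income-secure region;
        other regions receive the effect scaled by their security rank
        in [0, 1].
    planted_or
        Odds ratio planted in the survey generator (changed work environment,
        above- vs at/below-median income).
    noise_sd
        SD of the Gaussian per-slot noise on per-connection rates (bytes).
    children_download_effect
        Additional per-connection download volume (bytes per 30 min) at
        proportion-of-families-with-children = 1, applied to every slot in
        every period; models children's online activity dominating baseline
        downloads.
    household_level_sd
        Relative SD of a per-region multiplicative usage-level factor
        applied to the diurnal profile (truncated below at 0.3); models
        stable between-region differences in household internet use.
    region_effect_sd
        SD of an idiosyncratic per-region lockdown disturbance added to
        daytime per-connection means; models heterogeneous behavioural
        responses beyond the occupation gradient.
    min_connections
        Privacy floor: regions report at least this many active connections.
    """

    seed: int = 0
    n_regions: int = 200
    n_occupations: int = 300
    persons_per_region: int = 2000
    baseline_days: int = 51
    wave_days: int = 7
    baseline_start: date = date(2019, 10, 10)
    wave_start: date = date(2020, 4, 18)
    planted_rho_security_wfh: float = 0.8
    planted_rho_security_children: float = -0.4
    planted_upload_effect: float = 4_800_000.0
    planted_or: float = 2.15
    noise_sd: float = 2_000_000.0
    region_effect_sd: float = 0.0
    children_download_effect: float = 120_000_000.0
    household_level_sd: float = 0.12
    min_connections: int = 50

    def __post_init__(self) -> None:
        for name in ("n_regions", "n_occupations", "persons_per_region",
                     "baseline_days", "wave_days", "min_connections"):
            _require(int(getattr(self, name)) >= 1, name, "must be a count >= 1")
        for name in ("planted_rho_security_wfh", "planted_rho_security_children"):
            _require(-1.0 <= getattr(self, name) <= 1.0, name,
                     "must be a correlation in [-1, 1]")
        _require(self.planted_or > 0, "planted_or", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.region_effect_sd >= 0, "region_effect_sd", "must be >= 0")
        _require(self.children_download_effect >= 0, "children_download_effect",
                 "must be >= 0 bytes")
        _require(self.household_level_sd >= 0, "household_level_sd",
                 "must be >= 0")
        _require(self.planted_upload_effect >= 0, "planted_upload_effect",
                 "must be >= 0 bytes")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["baseline_start"] = self.baseline_start.isoformat()
        d["wave_start"] = self.wave_start.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        for key in ("baseline_start", "wave_start"):
            if key in d and isinstance(d[key], str):
                d[key] = date.fromisoformat(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)
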