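"""Synthetic study generator.

Emulates the five restricted inputs of the analysis — individual employment
records with occupation-level earnings, a binary work-from-home lookup with
taxonomy crosswalks, per-region occupation distributions with demographic
covariates, 30-minute household internet telemetry, and an individual survey
— with a known planted statistical structure so every downstream stage can
be validated offline.

The diurnal traffic curve follows the canonical household shape: a pre-dawn
minimum between 4:30 and 5:30 a.m., a daytime plateau from 9 a.m. to noon,
and an evening peak between 8:30 and 10 p.m.  Default slot means are integer
multiples of 48000 bytes so that, at zero noise, every windowed average is
exact in double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ScenarioConfig

__all__ = [
    "DiurnalProfile",
    "RegionData",
    "generate_occupations",
    "generate_regions",
    "generate_traffic",
    "generate_survey",
    "expand_employment_records",
    "build_wfh_crosswalk",
    "security_rank01",
    "region_effect_sd_for_target_rho",
    "daytime_weekday_intervals",
    "write_scenario",
]

# Half-hour slot indices of the characteristic windows (slot i starts at
# i * 30 minutes past midnight; windows are half-open on start labels).
PREDAWN_SLOTS = (9, 10)                 # 04:30, 05:00
DAYTIME_SLOTS = tuple(range(18, 24))    # 09:00 .. 11:30
EVENING_SLOTS = (41, 42, 43)            # 20:30, 21:00, 21:30

# Relative diurnal shape, one value per half-hour starting at midnight.
_SHAPE = np.array([
    0.55, 0.45, 0.38, 0.32, 0.27, 0.23, 0.20, 0.17,   # 00:00-03:30
    0.15, 0.13, 0.135, 0.15, 0.18, 0.22, 0.28, 0.34,  # 04:00-07:30
    0.40, 0.45, 0.50, 0.52, 0.53, 0.54, 0.54, 0.55,   # 08:00-11:30
    0.56, 0.57, 0.57, 0.58, 0.58, 0.59, 0.60, 0.62,   # 12:00-15:30
    0.65, 0.68, 0.72, 0.76, 0.80, 0.84, 0.88, 0.92,   # 16:00-19:30
    0.96, 0.98, 1.00, 0.99, 0.95, 0.88, 0.78, 0.66,   # 20:00-23:30
])

_BYTES_QUANTUM = 48_000.0  # default slot means snap to this grid


@dataclass(frozen=True)
class DiurnalProfile:
    """Mean per-connection volume per half-hour slot, plus day-type scales.

    ``slot_means`` holds 48 non-negative values (bytes per 30 min per active
    connection), one per half-hour of the day starting at midnight.  The
    minimum must fall in the 4:30-5:30 a.m. slots and the maximum in the
    8:30-10 p.m. slots, matching the observed household curve.
    """

    slot_means: np.ndarray
    weekend_scale: float = 1.10
    holiday_scale: float = 1.15

    def __post_init__(self) -> None:
        means = np.asarray(self.slot_means, dtype=float)
        object.__setattr__(self, "slot_means", means)
        if means.shape != (48,):
            raise ValueError("slot_means: must have exactly 48 half-hour values")
        if (means < 0).any():
            raise ValueError("slot_means: volumes must be non-negative")
        if int(np.argmin(means)) not in PREDAWN_SLOTS:
            raise ValueError("slot_means: daily minimum must fall in 4:30-5:30 a.m.")
        if int(np.argmax(means)) not in EVENING_SLOTS:
            raise ValueError("slot_means: daily maximum must fall in 8:30-10 p.m.")

    @classmethod
    def default(cls, direction: str = "download", *, weekend_scale: float = 1.10,
                holiday_scale: float = 1.15) -> "DiurnalProfile":
        """Typical household curve: ~240 MB (download) or ~24 MB (upload)
        per connection per half hour at the evening peak."""
        peak = {"download": 2.4e8, "upload": 2.4e7}[direction]
        means = np.round(_SHAPE * peak / _BYTES_QUANTUM) * _BYTES_QUANTUM
        return cls(means, weekend_scale=weekend_scale, holiday_scale=holiday_scale)


class RegionData(NamedTuple):
    """Region-level synthetic tables."""

    regions: pd.DataFrame            # one row per region, covariates + truth
    occupation_counts: pd.DataFrame  # long: region_id, occupation_code, count
    adjacency: pd.DataFrame          # symmetric pairs: region_id, neighbour_id


# ---------------------------------------------------------------------------
# occupations


def generate_occupations(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the occupation-level truth table.

    Each occupation gets a 4-digit code, average weekly earnings, a realised
    proportion of securely employed respondents, and a binary work-from-home
    flag whose point-biserial correlation with the income security index
    (the product of ``prop_secure`` and earnings rescaled to the sample
    maximum) targets ``planted_rho_security_wfh``.

    The flag is drawn from a latent threshold model on the normal scores of
    the index; the latent correlation is calibrated against the in-sample
    linearity of the index so the realised point-biserial correlation tracks
    the planted one (capped at the attainable maximum for a binary variable).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_occupations

    codes = rng.choice(np.arange(1000, 9000), size=n, replace=False)
    codes = np.sort(codes)
    code_str = np.array([f"{c:04d}" for c in codes])

    latent = rng.standard_normal(n)
    earnings = np.round(np.exp(6.9 + 0.30 * (0.8 * latent + 0.6 * rng.standard_normal(n))))
    earnings = np.maximum(earnings, 100.0)  # AUD / week

    p_secure = sps.norm.cdf(0.35 + 0.9 * (0.8 * latent + 0.6 * rng.standard_normal(n)))
    n_resp = rng.integers(12, 80, size=n)
    n_secure = rng.binomial(n_resp, p_secure)
    prop_secure = n_secure / n_resp

    index = prop_secure * earnings / earnings.max()

    # latent threshold model for the binary WFH flag
    ranks = sps.rankdata(index, method="average")
    scores = sps.norm.ppf((ranks - 0.5) / n)
    if n >= 3 and np.std(index) > 0 and np.std(scores) > 0:
        linearity = float(np.corrcoef(index, scores)[0, 1])
    else:
        linearity = 1.0
    p_wfh = 0.45
    cut = sps.norm.ppf(1.0 - p_wfh)
    attainable = sps.norm.pdf(cut) / math.sqrt(p_wfh * (1.0 - p_wfh))
    rho = config.planted_rho_security_wfh
    r_lat = float(np.clip(rho / (attainable * linearity), -1.0, 1.0))
    lat = r_lat * scores + math.sqrt(max(0.0, 1.0 - r_lat**2)) * rng.standard_normal(n)
    wfh_flag = (lat > cut).astype(int)

    return pd.DataFrame({
        "occupation_code": code_str,
        "avg_weekly_earnings": earnings,
        "n_respondents": n_resp,
        "n_secure": n_secure,
        "prop_secure": prop_secure,
        "income_security": index,
        "wfh_flag": wfh_flag,
    })


def expand_employment_records(occupations: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Expand occupation-level respondent counts into individual records.

    Secure respondents are split between permanent and fixed-term contracts,
    insecure ones between casual and other insecure arrangements; the secure
    count per occupation is preserved exactly, so re-deriving ``prop_secure``
    from these records reproduces the truth table.
    """
    rng = np.random.default_rng(seed + 1)
    rows: list[tuple[str, str]] = []
    for code, n_resp, n_secure in zip(occupations["occupation_code"],
                                      occupations["n_respondents"],
                                      occupations["n_secure"]):
        secure_labels = np.where(rng.random(int(n_secure)) < 0.8,
                                 "permanent", "fixed_term")
        insecure_labels = np.where(rng.random(int(n_resp - n_secure)) < 0.75,
                                   "casual", "other_insecure")
        rows.extend((code, lab) for lab in secure_labels)
        rows.extend((code, lab) for lab in insecure_labels)
    return pd.DataFrame(rows, columns=["occupation_code", "contract_type"])


def build_wfh_crosswalk(occupations: pd.DataFrame, seed: int,
                        override_fraction: float = 0.10
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate the foreign-taxonomy WFH lookup and its crosswalk.

    Each 4-digit code is given 1-3 synthetic 6-digit children sharing the
    parent's binary flag, keyed to ISCO-style source codes.  A fraction of
    codes is withheld from the crosswalk and supplied through the manual
    override table instead, mirroring codes that fail to link.
    Returns ``(crosswalk, overrides)``.
    """
    rng = np.random.default_rng(seed + 2)
    xwalk_rows: list[tuple[str, str, int]] = []
    override_rows: list[tuple[str, int]] = []
    for i, (code, flag) in enumerate(zip(occupations["occupation_code"],
                                         occupations["wfh_flag"])):
        if rng.random() < override_fraction:
            override_rows.append((code, int(flag)))
            continue
        for child in range(1, int(rng.integers(1, 4)) + 1):
            xwalk_rows.append((f"I{1000 + i}{child}", f"{code}{child:02d}", int(flag)))
    crosswalk = pd.DataFrame(xwalk_rows,
                             columns=["source_code", "target_code", "wfh_flag"])
    overrides = pd.DataFrame(override_rows, columns=["occupation_code", "wfh_flag"])
    return crosswalk, overrides


# ---------------------------------------------------------------------------
# regions


def generate_regions(config: ScenarioConfig, occupations: pd.DataFrame) -> RegionData:
    """Generate regions on a grid with planted socioeconomic structure.

    Regions are laid on a ceil(sqrt(n)) x ceil(sqrt(n)) grid with rook
    contiguity.  Each region draws an occupation count vector (summing to
    ``persons_per_region``) from a multinomial whose weights tilt toward
    high-security occupations in proportion to a latent regional affluence,
    and a spatially smooth component of that affluence induces positive
    spatial autocorrelation of regional income security.  The proportion of
    families with children is generated to correlate with regional income
    security at ``planted_rho_security_children``.
    """
    if occupations.empty:
        raise ValueError("occupations: table must be non-empty")
    rng = np.random.default_rng(config.seed + 10)
    n = config.n_regions
    side = math.ceil(math.sqrt(n))

    gx, gy = np.divmod(np.arange(n), side)
    region_id = np.array([f"R{i:04d}" for i in range(n)])

    # latent affluence: smooth east-west gradient + local noise, so that
    # regional measures exhibit positive spatial autocorrelation
    gradient = (gy - gy.mean()) / max(gy.std(), 1.0)
    affluence = 0.8 * gradient + 0.8 * rng.standard_normal(n)

    occ_index = occupations["income_security"].to_numpy()
    occ_scores = sps.norm.ppf(
        (sps.rankdata(occ_index, method="average") - 0.5) / len(occ_index))
    base_pop = rng.lognormal(0.0, 0.8, size=len(occ_index))
    logits = np.log(base_pop)[None, :] + 0.55 * affluence[:, None] * occ_scores[None, :]
    weights = np.exp(logits - logits.max(axis=1, keepdims=True))
    weights /= weights.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(config.persons_per_region, w)
                        for w in weights])

    security = counts @ occ_index / config.persons_per_region
    wfh = counts @ occupations["wfh_flag"].to_numpy() / config.persons_per_region

    shat = (security - security.mean()) / security.std() if n > 1 and security.std() > 0 \
        else np.zeros(n)
    rho_c = config.planted_rho_security_children
    raw = rho_c * shat + math.sqrt(max(0.0, 1.0 - rho_c**2)) * rng.standard_normal(n)
    prop_children = np.clip(0.42 + 0.13 * raw, 0.02, 0.95)
    prop_internet = np.clip(0.92 + 0.04 * (0.5 * shat
                                           + 0.5 * rng.standard_normal(n)), 0.55, 1.0)

    regions = pd.DataFrame({
        "region_id": region_id,
        "grid_x": gx,
        "grid_y": gy,
        # split orthogonal to the smooth gradient: the two cities differ
        # only stochastically, not systematically
        "city": np.where(gx < side / 2, "city_a", "city_b"),
        "prop_families_children": prop_children,
        "prop_internet_connected": prop_internet,
        "income_security": security,
        "wfh_fraction": wfh,
    })

    counts_long = pd.DataFrame({
        "region_id": np.repeat(region_id, len(occ_index)),
        "occupation_code": np.tile(occupations["occupation_code"].to_numpy(), n),
        "count": counts.ravel(),
    })
    counts_long = counts_long[counts_long["count"] > 0].reset_index(drop=True)

    pairs: list[tuple[str, str]] = []
    coord_to_idx = {(x, y): i for i, (x, y) in enumerate(zip(gx, gy))}
    for i, (x, y) in enumerate(zip(gx, gy)):
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            j = coord_to_idx.get((x + dx, y + dy))
            if j is not None:
                pairs.append((region_id[i], region_id[j]))
    adjacency = pd.DataFrame(pairs, columns=["region_id", "neighbour_id"])

    return RegionData(regions, counts_long, adjacency)


# ---------------------------------------------------------------------------
# traffic


def security_rank01(security: np.ndarray) -> np.ndarray:
    """Rank-scale a vector to [0, 1]; the maximum maps to exactly 1."""
    security = np.asarray(security, dtype=float)
    n = len(security)
    if n == 1:
        return np.zeros(1)
    order = sps.rankdata(security, method="ordinal") - 1
    return order / (n - 1)


def _dates(start: date, days: int) -> np.ndarray:
    return np.array([start + timedelta(d) for d in range(days)])


def daytime_weekday_intervals(start: date, days: int) -> int:
    """Number of 9 a.m.-noon half-hour slots falling on weekdays."""
    return 6 * sum(1 for d in _dates(start, days) if d.weekday() < 5)


def generate_traffic(config: ScenarioConfig, regions: pd.DataFrame,
                     download_profile: DiurnalProfile | None = None,
                     upload_profile: DiurnalProfile | None = None) -> pd.DataFrame:
    """Generate 30-minute telemetry for the baseline and lockdown windows.

    Per-connection slot means follow the diurnal profile (weekend-scaled),
    scaled by a per-region household usage-level factor
    (``household_level_sd``); downloads additionally carry
    ``children_download_effect`` x proportion-of-families-with-children in
    every slot and period.  During the lockdown window the 9 a.m.-noon
    slots receive ``planted_upload_effect`` x (region security rank in
    [0,1]) in both directions plus a per-region Gaussian disturbance of SD
    ``region_effect_sd``.  I.i.d. Gaussian slot noise of SD ``noise_sd`` is
    added last; rates are truncated at zero and multiplied by the region's
    active connection count.  Since the usage level and children components
    are constant across periods they cancel exactly from absolute
    baseline-to-lockdown changes.
    """
    if config.baseline_days < 1 or config.wave_days < 1:
        raise ValueError("baseline_days/wave_days: windows must be non-empty")
    if regions.empty:
        raise ValueError("regions: table must be non-empty")
    if download_profile is None:
        download_profile = DiurnalProfile.default("download")
    if upload_profile is None:
        upload_profile = DiurnalProfile.default("upload")

    rng = np.random.default_rng(config.seed + 20)
    n = len(regions)
    dates = np.concatenate([_dates(config.baseline_start, config.baseline_days),
                            _dates(config.wave_start, config.wave_days)])
    n_days = len(dates)
    weekend = np.array([d.weekday() >= 5 for d in dates])
    in_wave = np.array([d >= config.wave_start for d in dates])
    daytime_mask = np.zeros(48, dtype=bool)
    daytime_mask[list(DAYTIME_SLOTS)] = True

    rank01 = security_rank01(regions["income_security"].to_numpy())

    connections = np.maximum(
        config.min_connections,
        np.round(config.persons_per_region / 2.6
                 * rng.uniform(0.85, 1.15, size=n)).astype(int))

    level = np.ones(n)
    if config.household_level_sd > 0:
        level = np.maximum(
            0.3, 1.0 + rng.normal(0.0, config.household_level_sd, size=n))
    if "prop_families_children" in regions.columns:
        children = regions["prop_families_children"].to_numpy()
    else:
        children = np.zeros(n)

    out: dict[str, np.ndarray] = {}
    for direction, profile in (("download", download_profile),
                               ("upload", upload_profile)):
        scale = np.where(weekend, profile.weekend_scale, 1.0)
        base = profile.slot_means[None, None, :] * scale[None, :, None]
        rates = level[:, None, None] * base
        rates = np.broadcast_to(rates, (n, n_days, 48)).copy()
        if direction == "download" and config.children_download_effect > 0:
            rates += config.children_download_effect * children[:, None, None]
        planted = config.planted_upload_effect * rank01
        wave_daytime = in_wave[None, :, None] & daytime_mask[None, None, :]
        rates += planted[:, None, None] * wave_daytime
        if config.region_effect_sd > 0:
            delta = rng.normal(0.0, config.region_effect_sd, size=n)
            rates += delta[:, None, None] * wave_daytime
        if config.noise_sd > 0:
            rates += rng.normal(0.0, config.noise_sd, size=rates.shape)
        np.maximum(rates, 0.0, out=rates)
        out[direction] = rates * connections[:, None, None]

    starts = (pd.to_datetime(dates).values[None, :, None].astype("datetime64[m]")
              + (np.arange(48) * 30).astype("timedelta64[m]")[None, None, :])
    starts = np.broadcast_to(starts, (n, n_days, 48))

    return pd.DataFrame({
        "region_id": np.repeat(regions["region_id"].to_numpy(), n_days * 48),
        "interval_start": starts.ravel(),
        "download_bytes": out["download"].ravel(),
        "upload_bytes": out["upload"].ravel(),
        "active_connections": np.repeat(connections, n_days * 48),
    })


def region_effect_sd_for_target_rho(security: np.ndarray, target_rho: float,
                                    effect: float, noise_sd: float,
                                    n_baseline_intervals: int,
                                    n_wave_intervals: int) -> float:
    """Per-region disturbance SD that plants a target correlation.

    Solves for the SD of the per-region lockdown disturbance such that the
    population correlation between regional income security and the measured
    daytime per-connection change equals ``target_rho``, given the planted
    rank-scaled effect, the slot noise, and the number of daytime intervals
    averaged in each window.
    """
    if not 0 < abs(target_rho) <= 1:
        raise ValueError("target_rho: must be a non-zero correlation")
    security = np.asarray(security, dtype=float)
    r = security_rank01(security)
    rho_sr = float(np.corrcoef(security, r)[0, 1])
    if abs(target_rho) >= rho_sr:
        raise ValueError(
            f"target_rho: |rho|={abs(target_rho):.3f} exceeds the attainable "
            f"{rho_sr:.3f} given rank-scaling of the effect")
    var_needed = (effect * r.std()) ** 2 * (rho_sr**2 / target_rho**2 - 1.0)
    var_slot_noise = noise_sd**2 * (1.0 / n_wave_intervals
                                    + 1.0 / n_baseline_intervals)
    var_region = var_needed - var_slot_noise
    if var_region < 0:
        raise ValueError("noise_sd: slot noise alone exceeds the target "
                         "correlation's noise budget")
    return math.sqrt(var_region)


# ---------------------------------------------------------------------------
# survey


def generate_survey(config: ScenarioConfig, n_above: int = 411,
                    n_below: int = 464, p_reference: float = 0.20) -> pd.DataFrame:
    """Generate individual survey responses with a planted odds ratio.

    The reference (at/below-median income) group answers "yes" to the
    changed-work-environment question with probability ``p_reference``; the
    above-median group's probability is set so the population odds ratio
    equals ``planted_or``.  Default group sizes match a survey of 875
    Victorian respondents.
    """
    rng = np.random.default_rng(config.seed + 30)
    odds_ref = p_reference / (1.0 - p_reference)
    odds_above = config.planted_or * odds_ref
    p_above = odds_above / (1.0 + odds_above)

    group = np.concatenate([np.repeat("above_median", n_above),
                            np.repeat("at_or_below_median", n_below)])
    p = np.concatenate([np.full(n_above, p_above), np.full(n_below, p_reference)])
    yes = rng.random(n_above + n_below) < p
    return pd.DataFrame({
        "respondent_id": np.arange(n_above + n_below),
        "income_group": group,
        "changed_work_environment": np.where(yes, "yes", "no"),
    })


# ---------------------------------------------------------------------------
# scenario export


def write_scenario(config: ScenarioConfig, outdir) -> dict[str, pd.DataFrame]:
    """Generate every input table and write the scenario to ``outdir``.

    Writes employment_records, occupation_earnings, wfh_crosswalk,
    wfh_overrides, region_occupation_counts, region_covariates, adjacency,
    traffic and survey CSVs plus the scenario YAML; returns the tables.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    occupations = generate_occupations(config)
    records = expand_employment_records(occupations, config.seed)
    crosswalk, overrides = build_wfh_crosswalk(occupations, config.seed)
    region_data = generate_regions(config, occupations)
    traffic = generate_traffic(config, region_data.regions)
    survey = generate_survey(config)

    earnings = occupations[["occupation_code", "avg_weekly_earnings"]]
    covariates = region_data.regions.drop(
        columns=["income_security", "wfh_fraction"])

    tables = {
        "employment_records": records,
        "occupation_earnings": earnings,
        "wfh_crosswalk": crosswalk,
        "wfh_overrides": overrides,
        "region_occupation_counts": region_data.occupation_counts,
        "region_covariates": covariates,
        "adjacency": region_data.adjacency,
        "traffic": traffic,
        "survey": survey,
    }
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    config.to_yaml(outdir / "scenario.yaml")
    return tables
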