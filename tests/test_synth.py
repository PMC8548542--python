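"""Synthetic generator: determinism, invariants, and planted structure."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from homenet.config import ScenarioConfig
from homenet.stats import fisher_exact_or, ContingencyTable
from homenet.synth import (
    DAYTIME_SLOTS,
    EVENING_SLOTS,
    PREDAWN_SLOTS,
    DiurnalProfile,
    build_wfh_crosswalk,
    expand_employment_records,
    generate_occupations,
    generate_regions,
    generate_survey,
    generate_traffic,
    security_rank01,
    write_scenario,
)
from homenet.traffic import AnalysisPeriod, per_connection_rates, period_metrics


class TestConfig:
    def test_invalid_fields_rejected_by_name(self):
        with pytest.raises(ValueError, match="n_regions"):
            ScenarioConfig(n_regions=0)
        with pytest.raises(ValueError, match="planted_rho_security_wfh"):
            ScenarioConfig(planted_rho_security_wfh=1.5)
        with pytest.raises(ValueError, match="planted_or"):
            ScenarioConfig(planted_or=0.0)

    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "scenario.yaml"
        small_config.to_yaml(path)
        assert ScenarioConfig.from_yaml(path) == small_config


class TestDiurnalProfile:
    def test_shape_invariants(self):
        for direction in ("download", "upload"):
            p = DiurnalProfile.default(direction)
            assert p.slot_means.shape == (48,)
            assert (p.slot_means >= 0).all()
            assert int(np.argmin(p.slot_means)) in PREDAWN_SLOTS
            assert int(np.argmax(p.slot_means)) in EVENING_SLOTS

    def test_misplaced_minimum_rejected(self):
        means = DiurnalProfile.default("download").slot_means.copy()
        means[0] = 0.0  # midnight minimum is not a household curve
        with pytest.raises(ValueError, match="4:30-5:30"):
            DiurnalProfile(means)


class TestOccupations:
    def test_determinism_byte_identical(self, small_config):
        a = generate_occupations(small_config)
        b = generate_occupations(small_config)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_column_ranges(self, occupations):
        assert (occupations["avg_weekly_earnings"] > 0).all()
        assert occupations["prop_secure"].between(0, 1).all()
        assert occupations["income_security"].between(0, 1).all()
        assert occupations["wfh_flag"].isin((0, 1)).all()

    def test_perfect_correlation_orders_two_occupations(self):
        cfg = ScenarioConfig(seed=0, n_occupations=2,
                             planted_rho_security_wfh=1.0)
        occ = generate_occupations(cfg)
        top = occ.loc[occ["income_security"].idxmax()]
        bottom = occ.loc[occ["income_security"].idxmin()]
        assert top["wfh_flag"] == 1 and bottom["wfh_flag"] == 0

    def test_planted_point_biserial_recovered(self):
        # Monte-Carlo over 20 seeds at the default planted value 0.8
        rhos = []
        for seed in range(20):
            occ = generate_occupations(
                ScenarioConfig(seed=seed, n_occupations=300,
                               planted_rho_security_wfh=0.8))
            rhos.append(np.corrcoef(occ["income_security"],
                                    occ["wfh_flag"])[0, 1])
        assert abs(np.mean(rhos) - 0.8) < 0.1

    def test_records_reproduce_secure_counts(self, small_config, occupations):
        records = expand_employment_records(occupations, small_config.seed)
        secure = records["contract_type"].isin({"permanent", "fixed_term"})
        got = (records.assign(s=secure).groupby("occupation_code")["s"]
               .agg(["size", "sum"]))
        merged = occupations.set_index("occupation_code").join(got)
        assert (merged["n_respondents"] == merged["size"]).all()
        assert (merged["n_secure"] == merged["sum"]).all()

    def test_crosswalk_covers_every_code(self, small_config, occupations):
        crosswalk, overrides = build_wfh_crosswalk(occupations,
                                                   small_config.seed)
        covered = (set(crosswalk["target_code"].str[:4])
                   | set(overrides["occupation_code"]))
        assert covered == set(occupations["occupation_code"])


class TestRegions:
    def test_single_region_has_empty_adjacency(self, occupations):
        cfg = ScenarioConfig(seed=1, n_regions=1, n_occupations=40,
                             persons_per_region=500)
        reg = generate_regions(cfg, occupations)
        assert reg.adjacency.empty

    def test_counts_conserve_population(self, small_config, region_data):
        sums = region_data.occupation_counts.groupby("region_id")["count"].sum()
        assert (sums == small_config.persons_per_region).all()

    def test_covariates_in_range(self, region_data):
        r = region_data.regions
        assert r["prop_families_children"].between(0, 1).all()
        assert r["prop_internet_connected"].between(0, 1).all()

    def test_adjacency_symmetric_no_self_loops(self, region_data):
        adj = region_data.adjacency
        pairs = set(zip(adj["region_id"], adj["neighbour_id"]))
        assert all((b, a) in pairs for a, b in pairs)
        assert all(a != b for a, b in pairs)

    def test_planted_children_correlation(self):
        rhos = []
        for seed in range(10):
            cfg = ScenarioConfig(seed=seed, n_regions=200, n_occupations=100,
                                 planted_rho_security_children=-0.4)
            occ = generate_occupations(cfg)
            reg = generate_regions(cfg, occ)
            rhos.append(np.corrcoef(reg.regions["income_security"],
                                    reg.regions["prop_families_children"])[0, 1])
        assert all(-0.55 <= r <= -0.25 for r in rhos)


class TestTraffic:
    def test_null_effect_gives_equal_periods(self, exact_config, flat_profiles):
        cfg = exact_config.replace(planted_upload_effect=0.0)
        occ = generate_occupations(cfg)
        reg = generate_regions(cfg, occ)
        traffic = generate_traffic(cfg, reg.regions, *flat_profiles)
        rates, _ = per_connection_rates(traffic, cfg.min_connections)
        base = AnalysisPeriod("baseline", cfg.baseline_start,
                              cfg.baseline_start + timedelta(13))
        wave = AnalysisPeriod("wave1", cfg.wave_start,
                              cfg.wave_start + timedelta(6))
        mb = period_metrics(rates, base).set_index(["region_id", "direction"])
        mw = period_metrics(rates, wave).set_index(["region_id", "direction"])
        for metric in ("daytime_avg", "predawn_min", "evening_max"):
            assert (mb[metric] == mw[metric]).all()

    def test_slot_minimum_in_predawn_window(self, exact_traffic):
        _, traffic = exact_traffic
        ts = pd.DatetimeIndex(traffic["interval_start"])
        slot = (ts.hour * 60 + ts.minute) // 30
        by_slot = traffic.groupby(np.asarray(slot))["download_bytes"].mean()
        assert int(by_slot.idxmin()) in PREDAWN_SLOTS
        assert int(by_slot.idxmax()) in EVENING_SLOTS

    def test_connection_floor_respected(self, exact_traffic):
        _, traffic = exact_traffic
        assert (traffic["active_connections"] >= 50).all()
        assert (traffic[["download_bytes", "upload_bytes"]] >= 0).all().all()

    def test_determinism_byte_identical(self, exact_config, flat_profiles):
        occ = generate_occupations(exact_config)
        reg = generate_regions(exact_config, occ)
        a = generate_traffic(exact_config, reg.regions, *flat_profiles)
        b = generate_traffic(exact_config, reg.regions, *flat_profiles)
        assert a.equals(b)


class TestSurvey:
    def test_planted_unit_odds_ratio_bounds(self):
        cfg = ScenarioConfig(seed=4, planted_or=1.0)
        survey = generate_survey(cfg, n_above=5000, n_below=5000)
        t = ContingencyTable.from_survey(survey)
        sample_or = (t.a * t.d) / (t.b * t.c)
        assert 0.85 <= sample_or <= 1.18

    def test_planted_or_converges(self):
        ors = []
        for seed in range(10):
            cfg = ScenarioConfig(seed=seed, planted_or=2.15)
            s = generate_survey(cfg, n_above=20000, n_below=20000)
            t = ContingencyTable.from_survey(s)
            ors.append((t.a * t.d) / (t.b * t.c))
        assert abs(np.mean(ors) - 2.15) < 0.15

    def test_zero_yes_group_flagged_not_crashed(self):
        t = ContingencyTable(a=0, b=10, c=5, d=5)
        res = fisher_exact_or(t)
        assert res.degenerate and res.odds_ratio == 0.0
        assert 0 <= res.p_two_tailed <= 1


class TestScenarioExport:
    def test_write_scenario_byte_identical_across_runs(self, tmp_path):
        cfg = ScenarioConfig(seed=9, n_regions=4, n_occupations=12,
                             persons_per_region=300, baseline_days=2,
                             wave_days=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_scenario(cfg, d1)
        write_scenario(cfg, d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_security_rank01_endpoints():
    r = security_rank01(np.array([5.0, 1.0, 3.0]))
    assert r[np.argmax([5.0, 1.0, 3.0])] == 1.0
    assert r.min() == 0.0 and set(r) == {0.0, 0.5, 1.0}
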