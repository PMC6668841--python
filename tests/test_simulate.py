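import math

import numpy as np
import pandas as pd
import pytest

from vistl.catalogue import Group, default_catalogue
from vistl.simulate import (
    CohortConfig,
    EmissionParams,
    _simulate_severity_matrix,
    cohort_config_from_dict,
    cohort_config_to_dict,
    default_emissions,
    emit_observations,
    generate_cohort,
    localized_signal_config,
    null_variables,
    read_cohort_csv,
    signal_variables,
    simulate_severity,
    write_cohort_csv,
)


def _quiet_config(**kw):
    base = dict(sev_noise_sd=0.0, sev_trend_sd=0.0, sev_init_sd=0.0, sev_drift=0.0)
    base.update(kw)
    return CohortConfig(**base)


class TestSeverityProcess:
    def test_degenerate_process_is_constant_at_baseline(self, rng):
        cfg = _quiet_config()
        s = simulate_severity(cfg, "ICU", 48, rng)
        assert np.allclose(s, cfg.sev_baseline["ICU"])

    def test_same_seed_gives_identical_trace(self):
        cfg = CohortConfig()
        a = simulate_severity(cfg, "ward", 48, np.random.default_rng(5))
        b = simulate_severity(cfg, "ward", 48, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_short_horizon_rejected(self, rng):
        with pytest.raises(ValueError, match="48"):
            simulate_severity(CohortConfig(), "ward", 24, rng)

    def test_location_baseline_ordering_monte_carlo(self):
        """ICU trajectories run higher than ward, ward higher than 'other',
        averaged over 10,000 seeded trajectories each."""
        cfg = CohortConfig()
        rng = np.random.default_rng(99)
        means = {}
        for li, loc in enumerate(["ward", "ICU", "other"]):
            locs = np.full(10_000, ("ward", "ED", "ICU", "other").index(loc))
            means[loc] = _simulate_severity_matrix(cfg, locs, 48, rng).mean()
        assert means["ICU"] > means["ward"] > means["other"]

    def test_scalar_and_vectorized_paths_agree_in_distribution(self):
        cfg = CohortConfig()
        scalar = np.mean([simulate_severity(cfg, "ED", 48, np.random.default_rng(i)).mean()
                          for i in range(300)])
        locs = np.full(5000, 1)
        vec = _simulate_severity_matrix(cfg, locs, 48, np.random.default_rng(0)).mean()
        assert abs(scalar - vec) < 0.05


class TestEmission:
    def test_degenerate_emission_hits_normal_value(self, demo_catalogue, rng):
        """With zero link and zero noise every continuous value equals the
        variable's normal resting value."""
        emissions = {
            name: EmissionParams(p.rate_per_h, "linear", 0.0, 0.0)
            if p.mode in ("linear", "avpu", "gcs") else p
            for name, p in default_emissions(demo_catalogue).items()
        }
        cfg = _quiet_config(emissions=emissions)
        trace = np.zeros(48)
        obs = emit_observations(trace, demo_catalogue, cfg, rng)
        cont = obs[obs["variable"].map(
            lambda n: demo_catalogue[n].kind.value == "continuous")]
        for name, g in cont.groupby("variable"):
            assert np.allclose(g["value"], demo_catalogue[name].normal_value), name

    def test_higher_abnormal_mean_rises_with_severity(self, demo_catalogue):
        cfg = CohortConfig()
        hi = [emit_observations(np.full(48, 2.5), demo_catalogue, cfg,
                                np.random.default_rng(i)) for i in range(20)]
        lo = [emit_observations(np.zeros(48), demo_catalogue, cfg,
                                np.random.default_rng(1000 + i)) for i in range(20)]
        hi = pd.concat(hi)
        lo = pd.concat(lo)
        for var in ("lactate", "morse_score", "bun"):
            assert hi.loc[hi.variable == var, "value"].mean() > \
                lo.loc[lo.variable == var, "value"].mean()

    def test_values_respect_plausible_range(self, demo_catalogue, rng):
        cfg = CohortConfig()
        obs = emit_observations(np.full(48, 5.0), demo_catalogue, cfg, rng)
        for name, g in obs.groupby("variable"):
            spec = demo_catalogue[name]
            if spec.plausible_range:
                lo, hi = spec.plausible_range
                assert g["value"].between(lo, hi).all(), name

    def test_every_vital_observed_in_first_hour(self, demo_catalogue, rng):
        cfg = CohortConfig()
        obs = emit_observations(np.zeros(48), demo_catalogue, cfg, rng)
        vitals = [v.name for v in demo_catalogue if v.group is Group.VITALS]
        first_hour = obs[obs["time_h"] < 1.0]
        assert set(vitals) <= set(first_hour["variable"])

    def test_unknown_variable_emission_rejected(self, demo_catalogue, rng):
        emissions = default_emissions(demo_catalogue)
        emissions.pop("heart_rate")
        cfg = CohortConfig(emissions=emissions)
        with pytest.raises(ValueError, match="heart_rate"):
            emit_observations(np.zeros(48), demo_catalogue, cfg, rng)

    def test_signal_and_null_channel_designation(self, demo_catalogue):
        sig = set(signal_variables(demo_catalogue))
        null = set(null_variables(demo_catalogue))
        assert "lactate" in sig and "sodium" in null
        assert not sig & null


class TestGenerateCohort:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="n_admissions"):
            generate_cohort(CohortConfig(n_admissions=0))

    def test_invalid_config_names_offending_field(self):
        with pytest.raises(ValueError, match="location_probs"):
            generate_cohort(CohortConfig(n_admissions=5,
                                         location_probs=(0.5, 0.5, 0.5, 0.5)))

    def test_pure_intercept_death_rate(self):
        """With all outcome coefficients zeroed, deaths are iid Bernoulli at
        the intercept's probability."""
        p = 0.025
        cfg = CohortConfig(n_admissions=30_000, seed=3,
                           outcome_intercept=math.log(p / (1 - p)),
                           outcome_beta_sev=0.0, outcome_beta_age=0.0,
                           outcome_beta_female=0.0)
        cohort = generate_cohort(cfg, with_observations=False)
        rate = (cohort.admissions["outcome"] == "died").mean()
        assert abs(rate - p) < 3 * math.sqrt(p * (1 - p) / 30_000)

    def test_reproducible_from_seed(self):
        cfg = CohortConfig(n_admissions=100, seed=11)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.admissions, b.admissions)
        pd.testing.assert_frame_equal(a.observations, b.observations)

    def test_monotone_risk_in_severity_coefficient(self):
        rates = []
        for beta in (0.5, 1.7, 3.0):
            cfg = CohortConfig(n_admissions=20_000, seed=8, outcome_beta_sev=beta)
            cohort = generate_cohort(cfg, with_observations=False)
            rates.append((cohort.admissions["outcome"] == "died").mean())
        assert rates[0] < rates[1] < rates[2]

    def test_admission_invariants(self, small_cohort):
        adm = small_cohort.admissions
        assert (adm["los_days"] >= 2).all()
        assert adm["age"].between(18, 100).all()
        assert set(adm["outcome"]) <= {"died", "alive"}

    def test_record_protocol(self, small_cohort):
        rec = small_cohort[0]
        assert rec.id == small_cohort.ids[0]
        assert len(rec.latent_trace) == 48
        assert {"variable", "time_h", "value"} <= set(rec.observations.columns)
        obs_list = rec.observation_list()
        assert len(obs_list) == len(rec.observations)

    def test_localized_signal_config_delinks_everything_else(self):
        cfg = localized_signal_config(["lactate"], n_admissions=10, seed=0)
        cat = default_catalogue("demo")
        sig = signal_variables(cat, cfg.emissions)
        assert sig == ["lactate"]
        assert len(set(cfg.sev_baseline.values())) == 1


class TestCsvRoundTrip:
    def test_round_trip_is_lossless(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_admissions=30, seed=2))
        a, o = tmp_path / "admissions.csv", tmp_path / "observations.csv"
        write_cohort_csv(cohort, a, o)
        back = read_cohort_csv(a, o)
        pd.testing.assert_frame_equal(
            cohort.admissions.reset_index(drop=True),
            back.admissions[cohort.admissions.columns].reset_index(drop=True),
            check_dtype=False, check_categorical=False)
        orig = cohort.observations.sort_values(["id", "variable", "time_h"])
        got = back.observations.sort_values(["id", "variable", "time_h"])
        assert len(orig) == len(got)
        np.testing.assert_allclose(
            orig["value"].to_numpy(dtype=float), got["value"].to_numpy(dtype=float),
            atol=1e-4)

    def test_negative_time_rejected_with_row(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_admissions=5, seed=2))
        a, o = tmp_path / "a.csv", tmp_path / "o.csv"
        write_cohort_csv(cohort, a, o)
        obs = pd.read_csv(o)
        obs.loc[3, "time_h"] = -1.0
        obs.to_csv(o, index=False)
        with pytest.raises(ValueError, match="row 3"):
            read_cohort_csv(a, o)

    def test_unknown_variable_rejected(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_admissions=5, seed=2))
        a, o = tmp_path / "a.csv", tmp_path / "o.csv"
        write_cohort_csv(cohort, a, o)
        obs = pd.read_csv(o)
        obs.loc[0, "variable"] = "not_a_variable"
        obs.to_csv(o, index=False)
        with pytest.raises(ValueError, match="unknown variable"):
            read_cohort_csv(a, o)

    def test_admission_without_observations_accepted(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_admissions=5, seed=2))
        a, o = tmp_path / "a.csv", tmp_path / "o.csv"
        write_cohort_csv(cohort, a, o)
        obs = pd.read_csv(o)
        keep_id = obs["id"].iloc[0]
        obs = obs[obs["id"] != cohort.ids[3]]
        obs.to_csv(o, index=False)
        back = read_cohort_csv(a, o)
        assert len(back[3].observations) == 0

    def test_yaml_config_round_trip(self, tmp_path):
        from vistl.simulate import read_cohort_config_yaml, write_cohort_config_yaml
        cfg = CohortConfig(n_admissions=77, seed=5,
                           emissions=default_emissions(default_catalogue("demo")))
        path = tmp_path / "config.yaml"
        write_cohort_config_yaml(cfg, path)
        back = read_cohort_config_yaml(path)
        assert cohort_config_to_dict(back) == cohort_config_to_dict(cfg)
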