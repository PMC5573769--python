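"""Synthetic world: determinism, unbiasedness, cause accounting."""

import numpy as np
import pandas as pd
import pytest

from respburden.config import WorldConfig
from respburden.illness_death import RateSet, solve_illness_death
from respburden.synthworld import (
    generate_world,
    sample_cod,
    sample_encounters,
    sample_surveys,
)


class TestGenerateWorld:
    def test_deterministic_given_seed(self, tiny_config):
        w1 = generate_world(tiny_config)
        w2 = generate_world(tiny_config)
        pd.testing.assert_frame_equal(w1.cells, w2.cells)
        pd.testing.assert_frame_equal(w1.exposures, w2.exposures)
        pd.testing.assert_frame_equal(w1.sdi, w2.sdi)

    def test_zero_incidence_means_zero_prevalence_and_deaths(self):
        cfg = WorldConfig(n_locations=2, years=(2005,), n_draws=10, seed=0)
        for disease in cfg.baseline_rates:
            cfg.baseline_rates[disease]["i0"] = 0.0
            cfg.baseline_rates[disease]["i_floor"] = 0.0
        world = generate_world(cfg)
        assert (world.cells["p_copd"] == 0.0).all()
        assert (world.cells["deaths_copd"] == 0.0).all()
        assert (world.cells["p_asthma"] == 0.0).all()

    def test_prevalence_solves_from_cell_rates(self, tiny_world):
        """Band prevalence equals the illness-death solution of the stored
        band-constant rates (within solver tolerance)."""
        cfg = tiny_world.config
        cells = tiny_world.cells
        sub = cells[(cells["location"] == cfg.locations[0])
                    & (cells["sex"] == cfg.sexes[0])]
        knots = sub["age_start"].to_numpy(dtype=float)
        # bands below the first configured age carry the first band's rates
        rates = RateSet(
            knots=np.concatenate([[0.0], knots[1:]]),
            i=sub["i_copd"].to_numpy(),
            r=sub["r_copd"].to_numpy(),
            f=sub["f_copd"].to_numpy(),
            m=sub["m"].to_numpy(),
        )
        sol = solve_illness_death(rates, age_max=int(knots[-1]) + 5)
        for _, row in sub.iterrows():
            resolved = sol.band_average(row["age_start"], row["age_end"])
            assert resolved == pytest.approx(row["p_copd"], abs=1e-6)

    def test_cause_deaths_sum_to_all_cause(self, demo_world):
        cells = demo_world.cells
        total = (cells["deaths_copd"] + cells["deaths_asthma"]
                 + cells["deaths_other_resp"] + cells["deaths_other"])
        assert np.allclose(total, cells["deaths_all"], rtol=0, atol=1e-9)

    def test_higher_risk_exposure_raises_incidence(self, demo_world):
        """Incidence ordering follows the configured risk scalars."""
        sc = demo_world.risk_scalars
        cells = demo_world.cells
        merged = cells.merge(
            sc[sc["disease"] == "copd"], on=["location", "year"]
        )
        one_band = merged[(merged["age_start"] == 60.0)
                          & (merged["sex"] == "male")]
        order_by_scalar = one_band.sort_values("scalar_incidence")["i_copd"]
        assert order_by_scalar.is_monotonic_increasing

    def test_invalid_config_reported_by_name(self):
        with pytest.raises(ValueError, match="n_locations"):
            WorldConfig(n_locations=1)
        with pytest.raises(ValueError, match="n_draws"):
            WorldConfig(n_draws=1)
        with pytest.raises(ValueError, match="age_starts"):
            WorldConfig(age_starts=(10, 5))
        with pytest.raises(ValueError, match="survey_sample_size"):
            WorldConfig(survey_sample_size=0)


class TestSurveys:
    def test_noise_off_equals_biased_truth(self, tiny_world):
        cfg = tiny_world.config
        surveys = sample_surveys(tiny_world, noise=False)
        prev = surveys[(surveys["definition"] == "gold_postBD")
                       & (surveys["measure"] == "prevalence")]
        merged = prev.merge(
            tiny_world.cells,
            on=["location", "year", "sex", "age_start", "age_end"],
        )
        assert np.allclose(merged["mean"], merged["p_copd"], atol=1e-12)

    def test_definition_ratio_doubles_expectation(self, tiny_config):
        cfg = WorldConfig(**{**tiny_config.to_dict()})
        cfg.definitions["copd"]["lln_preBD"] = {
            "b0": float(np.log(2.0)), "b1": 0.0, "route": "crosswalk"
        }
        world = generate_world(cfg)
        surveys = sample_surveys(world, noise=False)
        prev = surveys[surveys["measure"] == "prevalence"]
        ref = prev[prev["definition"] == "gold_postBD"].set_index(
            ["location", "year", "sex", "age_start"])["mean"]
        alt = prev[prev["definition"] == "lln_preBD"].set_index(
            ["location", "year", "sex", "age_start"])["mean"]
        ratio = (alt / ref).dropna()
        assert np.allclose(ratio, 2.0, rtol=1e-9)

    def test_binomial_standard_error(self, tiny_world):
        surveys = sample_surveys(tiny_world, noise=False)
        n = tiny_world.config.survey_sample_size
        prev = surveys[surveys["measure"] == "prevalence"]
        p = np.clip(prev["mean"], 0.5 / n, 1 - 0.5 / n)
        assert np.allclose(prev["standard_error"],
                           np.sqrt(p * (1 - p) / n), rtol=1e-12)
        # the canonical case: n=400, p=0.2 -> SE 0.02
        assert np.sqrt(0.2 * 0.8 / 400) == pytest.approx(0.02)

    def test_unbiased_sampling_for_unbiased_definition(self, tiny_config, rng):
        cfg = WorldConfig(**{**tiny_config.to_dict()})
        cfg.definitions["copd"]["lln_preBD"] = {"b0": 0.0, "b1": 0.0,
                                                "route": "crosswalk"}
        world = generate_world(cfg)
        reps = []
        for _ in range(200):
            s = sample_surveys(world, definitions={"copd": ["lln_preBD"]},
                               noise=True, rng=rng, include_remission=False)
            reps.append(s["mean"].to_numpy())
        means = np.mean(reps, axis=0)
        truth = sample_surveys(world, definitions={"copd": ["lln_preBD"]},
                               noise=False, include_remission=False)["mean"]
        n = cfg.survey_sample_size
        mc_se = np.sqrt(truth * (1 - truth) / n / 200)
        assert np.all(np.abs(means - truth) < 3 * mc_se + 1e-9)

    def test_unknown_definition_rejected(self, tiny_world):
        with pytest.raises(ValueError, match="unknown case definition"):
            sample_surveys(tiny_world, definitions={"copd": ["fev_whatever"]})


class TestCoD:
    def test_noise_off_full_vr_equals_truth(self, tiny_config):
        cfg = WorldConfig(**{**tiny_config.to_dict()})
        cfg.va_fraction = (0.0, 0.0)
        cfg.vr_completeness = (1.0, 1.0)
        world = generate_world(cfg)
        cod = sample_cod(world, noise=False)
        merged = cod[cod["cause"] == "copd"].merge(
            world.cells, on=["location", "year", "sex", "age_start"]
        )
        assert np.allclose(merged["deaths"], merged["deaths_copd"])

    def test_full_va_hides_specific_causes(self, tiny_config):
        cfg = WorldConfig(**{**tiny_config.to_dict()})
        cfg.va_fraction = (1.0, 1.0)
        world = generate_world(cfg)
        cod = sample_cod(world, noise=False)
        assert set(cod["cause"]) == {"chronic_resp"}
        assert (cod["source_type"] == "VA").all()

    def test_completeness_thins_recorded_deaths(self, tiny_config, rng):
        """Recorded/true ratio averages the completeness across replicates."""
        cfg = WorldConfig(**{**tiny_config.to_dict()})
        cfg.va_fraction = (0.0, 0.0)
        cfg.vr_completeness = (0.8, 0.8)
        world = generate_world(cfg)
        truth_total = world.cells["deaths_all"].sum()
        ratios = []
        for _ in range(1000):
            cod = sample_cod(world, noise=True, rng=rng)
            ratios.append(cod["deaths"].sum() / truth_total)
        mean_ratio = np.mean(ratios)
        mc_se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean_ratio - 0.8) < 3 * mc_se


class TestEncounters:
    def test_combined_weight_is_multiplicative(self, tiny_config, rng):
        """With degenerate state distributions the combined weight is exactly
        1 - prod(1 - dw_c) over the individual's conditions."""
        cfg = WorldConfig(**{**tiny_config.to_dict()})
        cfg.state_distribution = {
            "copd": {"moderate": 1.0},
            "asthma": {"partially_controlled": 1.0},
        }
        world = generate_world(cfg)
        rec = sample_encounters(world, 4000, noise_sd=0.0, rng=rng)
        dw = cfg.disability_weights
        expected = 1.0 - (
            (1.0 - rec["has_copd"] * dw["copd"]["moderate"])
            * (1.0 - rec["has_asthma"] * dw["asthma"]["partially_controlled"])
            * (1.0 - rec["has_diabetes"] * cfg.comorbidities["diabetes"]["dw"])
            * (1.0 - rec["has_low_back_pain"]
               * cfg.comorbidities["low_back_pain"]["dw"])
        )
        assert np.allclose(rec["combined_dw"], expected, atol=1e-12)

    def test_no_conditions_zero_weight(self, tiny_world, rng):
        rec = sample_encounters(tiny_world, 2000, noise_sd=0.0, rng=rng)
        none = rec[(rec.filter(like="has_") == 0).all(axis=1)]
        assert len(none) > 0
        assert (none["combined_dw"] == 0.0).all()

    def test_positive_count_required(self, tiny_world):
        with pytest.raises(ValueError, match="n_individuals"):
            sample_encounters(tiny_world, 0)


class TestStreamIndependence:
    def test_identical_seed_identical_streams(self, tiny_config):
        w = generate_world(tiny_config)
        s1, s2 = sample_surveys(w), sample_surveys(w)
        pd.testing.assert_frame_equal(s1, s2)
        c1, c2 = sample_cod(w), sample_cod(w)
        pd.testing.assert_frame_equal(c1, c2)
        e1, e2 = sample_encounters(w, 500), sample_encounters(w, 500)
        pd.testing.assert_frame_equal(e1, e2)
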