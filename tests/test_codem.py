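"""Cause-of-death ensemble: component fits, weighting, squeezing."""

import numpy as np
import pandas as pd
import pytest

from respburden.codem_lite import (
    EnsembleWeights,
    ensemble_predict,
    fit_components,
    prepare_cod,
    score_oos,
    squeeze,
)
from respburden.drawcube import DrawCube


def _synthetic_cod(beta0=-8.0, beta1=2.0, n_loc=3, n_year=6, noise_sd=0.0,
                   seed=0):
    """Death records whose log rate is exactly beta0 + beta1 * smoking."""
    rng = np.random.default_rng(seed)
    rows = []
    for l in range(n_loc):
        for t in range(n_year):
            smoking = 0.1 + 0.05 * l + 0.02 * t
            for age in (50.0, 60.0, 70.0):
                rate = np.exp(beta0 + beta1 * smoking + 0.01 * (age - 50)
                              + (rng.normal(0, noise_sd) if noise_sd else 0.0))
                py = 1e6
                rows.append({
                    "location": f"loc_{l}", "year": 1990 + 5 * t, "sex": "male",
                    "age_start": age, "age_end": age + 5, "cause": "chronic_resp",
                    "deaths": rate * py - 0.5,  # continuity-corrected exactly
                    "person_years": py, "source_type": "VR",
                    "smoking": smoking, "allcause_rate": rate * 20,
                })
    df = pd.DataFrame(rows)
    return prepare_cod(df)


class TestFitComponents:
    def test_loglinear_recovery_without_noise(self):
        data = _synthetic_cod(beta1=2.0)
        models = fit_components(data, [("smoking",)], families=("log_rate",))
        coef = models[0].result.params["smoking"]
        assert coef == pytest.approx(2.0, abs=1e-6)

    def test_constant_covariate_dropped_with_reason(self, caplog):
        data = _synthetic_cod()
        data["flat"] = 1.0
        models = fit_components(
            data, [("smoking",), ("flat",)], families=("log_rate",)
        )
        assert len(models) == 1
        assert models[0].covariates == ("smoking",)
        assert any("flat" in r.message for r in caplog.records)

    def test_empty_covariate_subset_still_fits(self):
        models = fit_components(_synthetic_cod(), [()], families=("log_rate",))
        assert len(models) == 1

    def test_all_failures_abort(self):
        data = _synthetic_cod()
        with pytest.raises(RuntimeError, match="all component fits failed"):
            fit_components(data, [("missing_cov",)], families=("log_rate",))


class TestScoreOOS:
    def test_single_model_gets_weight_one(self):
        data = _synthetic_cod()
        models = fit_components(data, [("smoking",)], families=("log_rate",))
        w = score_oos(models, data, seed=3)
        assert w.weights.tolist() == [1.0]

    def test_better_model_gets_larger_weight(self):
        data = _synthetic_cod(noise_sd=0.05, seed=5)
        data["junk"] = np.sin(np.arange(len(data)))
        models = fit_components(
            data, [("smoking",), ("junk",)], families=("log_rate",)
        )
        w = score_oos(models, data, seed=3)
        assert w.rmse[0] < w.rmse[1]
        assert w.weights[0] > w.weights[1]

    def test_weights_normalised_and_nonnegative(self):
        with pytest.raises(ValueError):
            EnsembleWeights(weights=np.array([-0.1, 1.1]), rmse=np.zeros(2))
        ew = EnsembleWeights(weights=np.array([2.0, 2.0]), rmse=np.zeros(2))
        assert ew.weights.sum() == pytest.approx(1.0)

    def test_ensemble_not_worse_than_worst_component(self):
        """Weighted ensemble holdout RMSE <= max component RMSE, across
        simulated data sets."""
        for seed in range(20):
            data = _synthetic_cod(noise_sd=0.15, seed=seed)
            data["junk"] = np.cos(np.arange(len(data)) * seed)
            models = fit_components(
                data, [("smoking",), ("junk",)], families=("log_rate",)
            )
            w = score_oos(models, data, seed=seed, reps=2)
            obs = np.log(data["rate"] + 1e-12)
            preds = np.stack([m.predict_rate(data) for m in models])
            ens = np.log((w.weights[:, None] * preds).sum(axis=0) + 1e-12)
            rmse_ens = np.sqrt(np.mean((ens - obs) ** 2))
            worst = max(
                np.sqrt(np.mean((np.log(p + 1e-12) - obs) ** 2)) for p in preds
            )
            assert rmse_ens <= worst + 1e-9


class TestEnsemblePredict:
    def test_degenerate_weights_use_single_model(self):
        data = _synthetic_cod()
        models = fit_components(
            data, [("smoking",), ()], families=("log_rate",)
        )
        for m in models:
            m.resid_sd = 0.0  # deterministic predictive distributions
        w = EnsembleWeights(weights=np.array([1.0, 0.0]), rmse=np.zeros(2))
        cube = ensemble_predict(models, w, data, n_draws=20, seed=0)
        expected = models[0].predict_rate(data)
        assert np.allclose(cube.values, expected[:, None], rtol=1e-10)

    def test_location_without_data_still_predicted(self):
        data = _synthetic_cod()
        models = fit_components(data, [("smoking",)], families=("log_rate",))
        w = EnsembleWeights(weights=np.ones(1), rmse=np.zeros(1))
        targets = data.head(3).copy()
        targets["location"] = "loc_new"
        cube = ensemble_predict(models, w, targets, n_draws=10, seed=0)
        assert np.all(np.isfinite(cube.values)) and np.all(cube.values > 0)

    def test_missing_covariate_aborts(self):
        data = _synthetic_cod()
        models = fit_components(data, [("smoking",)], families=("log_rate",))
        w = EnsembleWeights(weights=np.ones(1), rmse=np.zeros(1))
        targets = data.drop(columns=["smoking"])
        with pytest.raises(ValueError, match="smoking"):
            ensemble_predict(models, w, targets, n_draws=5, seed=0)

    def test_draw_mean_matches_mixture_mean(self):
        data = _synthetic_cod()
        models = fit_components(
            data, [("smoking",), ()], families=("log_rate",)
        )
        w = EnsembleWeights(weights=np.array([0.7, 0.3]), rmse=np.zeros(2))
        n_draws = 1000
        cube = ensemble_predict(models, w, data, n_draws=n_draws, seed=11)
        # analytic lognormal mixture mean per cell
        mix = np.zeros(len(data))
        for wk, m in zip(w.weights, models):
            mean, sd = m.predict_link(data)
            mix += wk * np.exp(mean + sd**2 / 2.0)
        mc_se = cube.values.std(axis=1) / np.sqrt(n_draws)
        assert np.all(np.abs(cube.values.mean(axis=1) - mix) < 3 * mc_se + 1e-12)


class TestSqueeze:
    def _cube(self, vals):
        keys = pd.DataFrame({"cell": range(np.shape(vals)[0])})
        return DrawCube(keys, np.asarray(vals, dtype=float))

    def test_two_equal_children(self):
        children = {"a": self._cube([[2.0]]), "b": self._cube([[2.0]])}
        out = squeeze(children, self._cube([[3.0]]))
        assert out["a"].values[0, 0] == pytest.approx(1.5)
        assert out["b"].values[0, 0] == pytest.approx(1.5)

    def test_single_child_equals_envelope(self):
        out = squeeze({"only": self._cube([[5.0]])}, self._cube([[2.5]]))
        assert out["only"].values[0, 0] == pytest.approx(2.5)

    def test_ratios_preserved_and_envelope_conserved(self, rng):
        vals = {k: rng.uniform(0.1, 5.0, size=(8, 16)) for k in "abc"}
        envelope = rng.uniform(0.5, 10.0, size=(8, 16))
        out = squeeze({k: self._cube(v) for k, v in vals.items()},
                      self._cube(envelope))
        total = sum(c.values for c in out.values())
        assert np.allclose(total, envelope, rtol=0, atol=1e-12)
        ratio_before = vals["a"] / vals["b"]
        ratio_after = out["a"].values / out["b"].values
        assert np.allclose(ratio_before, ratio_after, rtol=1e-12)

    def test_zero_children_positive_envelope_aborts(self):
        with pytest.raises(ValueError, match="draw 0"):
            squeeze({"a": self._cube([[0.0]])}, self._cube([[1.0]]))
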