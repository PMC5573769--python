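"""Illness-death consistency meta-regression: EMR derivation, parameter
recovery, covariate constraints, posterior coverage."""

import numpy as np
import pandas as pd
import pytest

from respburden.dismod_lite import (
    DismodConfig,
    RateSet,
    derive_emr_datapoints,
    fit_consistent,
    predict,
    solve_illness_death,
)

KEYS = ["location", "year", "sex", "age_start", "age_end"]


def _point(measure, a0, a1, mean, se, location="loc", year=2005, sex="both",
           definition="reference"):
    return {
        "measure": measure, "location": location, "year": year, "sex": sex,
        "age_start": a0, "age_end": a1, "mean": mean, "standard_error": se,
        "definition": definition,
    }


def _simulate_dataset(rates: RateSet, age_bands, se_frac=0.0, rng=None,
                      definition="reference", mult=1.0, age_max=100,
                      location="loc", measures=("prevalence", "emr")):
    """Exact (or noisy) band-average datapoints from a known rate set."""
    sol = solve_illness_death(rates, age_max=age_max, n_substeps=2)
    fine = sol.ages
    # expand rates exactly as the model does: knot value of the whole year
    year_of_fine = np.minimum(fine.astype(int), age_max - 1)
    step = rates.expand(np.arange(age_max, dtype=float))
    points = []
    for a0, a1 in age_bands:
        mask = (fine >= a0) & (fine < a1)
        p = float(sol.p[mask].mean())
        f = float(step["f"][year_of_fine[mask]].mean())
        r = float(step["r"][year_of_fine[mask]].mean())
        for measure, truth in (("prevalence", p * mult), ("emr", f),
                               ("remission", r)):
            if measure not in measures:
                continue
            se = max(se_frac * truth, 1e-5)
            obs = truth + (rng.normal(0, se) if (rng and se_frac) else 0.0)
            points.append(_point(measure, a0, a1, max(obs, 0.0), se,
                                 location=location, definition=definition))
    return pd.DataFrame(points)


def _covariates(locations=("loc",), year=2005, risk=0.0, ldi=0.0):
    return pd.DataFrame(
        [{"location": l, "year": year, "risk_scalar": risk, "ldi": ldi}
         for l in locations]
    )


KNOTS = (0, 15, 30, 50, 70, 90)
TRUE_I = np.array([0.002, 0.004, 0.008, 0.012, 0.018, 0.022])
TRUE_F = np.array([0.004, 0.006, 0.010, 0.020, 0.035, 0.060])
BANDS = [(a, a + 10) for a in range(0, 100, 10)]


def _true_rates(m=0.01):
    return RateSet(knots=np.array(KNOTS, float), i=TRUE_I,
                   r=np.zeros(len(KNOTS)), f=TRUE_F,
                   m=np.full(len(KNOTS), m))


class TestDeriveEMR:
    def _df(self, rows):
        return pd.DataFrame(rows)

    def test_ratio_and_zero(self):
        csmr = self._df([
            _point("csmr", 50, 60, 0.001, 1e-4),
            _point("csmr", 60, 70, 0.0, 1e-4),
        ])
        prev = self._df([
            _point("prevalence", 50, 60, 0.05, 0.005),
            _point("prevalence", 60, 70, 0.08, 0.005),
        ])
        emr = derive_emr_datapoints(csmr, prev)
        assert emr["mean"].tolist() == pytest.approx([0.02, 0.0])

    def test_nonpositive_prevalence_skipped(self, caplog):
        csmr = self._df([_point("csmr", 50, 60, 0.001, 1e-4)])
        prev = self._df([_point("prevalence", 50, 60, 0.0, 0.005)])
        assert len(derive_emr_datapoints(csmr, prev)) == 0

    def test_delta_method_se_against_monte_carlo(self, rng):
        c, p = 0.002, 0.08
        sc, sp = 0.0002, 0.006
        csmr = self._df([_point("csmr", 50, 60, c, sc)])
        prev = self._df([_point("prevalence", 50, 60, p, sp)])
        emr = derive_emr_datapoints(csmr, prev)
        n = 100_000
        sim = rng.normal(c, sc, n) / rng.normal(p, sp, n)
        assert emr["standard_error"].iloc[0] == pytest.approx(sim.std(), rel=0.05)


class TestRecovery:
    def test_noise_free_recovery_within_two_percent(self):
        """Incidence and excess mortality recovered to < 2% relative error
        at every knot from exact prevalence + EMR band averages."""
        rates = _true_rates()
        data = _simulate_dataset(rates, BANDS, se_frac=0.0)
        cfg = DismodConfig(knots=KNOTS, remission="zero",
                           smoothness_sd={"i": 3.0, "r": 3.0, "f": 3.0})
        fit = fit_consistent(data, _covariates(), np.full(100, 0.01),
                             config=cfg, n_draws=50, seed=0)
        rec = fit.rate_set()
        assert np.all(np.abs(rec.i / TRUE_I - 1.0) < 0.02)
        assert np.all(np.abs(rec.f / TRUE_F - 1.0) < 0.02)

    def test_definition_multiplier_recovered(self):
        """A dataset biased by exp(0.3) in truth yields a fitted multiplier
        within 5% of exp(0.3)."""
        rates = _true_rates()
        ref = _simulate_dataset(rates, BANDS)
        biased = _simulate_dataset(rates, BANDS, definition="self_report",
                                   mult=np.exp(0.3),
                                   measures=("prevalence",))
        cfg = DismodConfig(knots=KNOTS, remission="zero",
                           study_covariates=("self_report",),
                           smoothness_sd={"i": 3.0, "r": 3.0, "f": 3.0})
        fit = fit_consistent(pd.concat([ref, biased], ignore_index=True),
                             _covariates(), np.full(100, 0.01),
                             config=cfg, n_draws=50, seed=0)
        assert fit.multipliers()["self_report"] == pytest.approx(
            np.exp(0.3), rel=0.05
        )

    def test_bounds_pinned_at_truth_reproduce_truth(self):
        """With the log-rate bounds degenerate at the true value the
        posterior collapses onto truth and predictions equal the
        illness-death solution of the true rates."""
        c = 0.01
        rates = RateSet(knots=[0.0], i=c, r=0.0, f=c, m=0.0)
        bands = [(40, 50), (60, 70)]
        data = _simulate_dataset(rates, bands)
        cfg = DismodConfig(knots=(0,), remission="zero",
                           log_rate_bounds=(np.log(c), np.log(c)),
                           maxiter=10)
        fit = fit_consistent(data, _covariates(), np.zeros(100),
                             config=cfg, n_draws=10, seed=0)
        preds = fit.predict_datapoints()
        assert np.allclose(preds, data["mean"].to_numpy(), rtol=1e-9)


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        rates = _true_rates()
        data = pd.concat([
            _simulate_dataset(rates, BANDS, location="A"),
            _simulate_dataset(rates, BANDS, location="B"),
        ], ignore_index=True)
        cov = _covariates(locations=("A", "B"))
        cfg = DismodConfig(knots=KNOTS, remission="zero",
                           smoothness_sd={"i": 3.0, "r": 3.0, "f": 3.0})
        return fit_consistent(data, cov, np.full(100, 0.01), config=cfg,
                              n_draws=400, seed=7)

    def test_consistency_prevalence_resolves_from_rates(self, fitted):
        """Feeding each draw's rates back through the solver reproduces the
        predicted prevalence (consistency is structural, not approximate)."""
        table = _covariates(locations=("A",))
        cubes = predict(fitted, table, [(40.0, 50.0), (70.0, 80.0)],
                        n_draws=5, m_background=np.full(100, 0.01))
        pr = fitted.problem
        for d in range(5):
            th = fitted.draws[d]
            rs = fitted.rate_set(th)
            rs.m = np.full(len(rs.knots), 0.01)
            sol = solve_illness_death(rs, n_substeps=2)
            for row, (a0, a1) in enumerate([(40.0, 50.0), (70.0, 80.0)]):
                mask = (sol.ages >= a0) & (sol.ages < a1)
                assert cubes["prevalence"].values[row, d] == pytest.approx(
                    float(sol.p[mask].mean()), abs=1e-6
                )

    def test_monotone_risk_covariate(self, fitted):
        table = pd.DataFrame([
            {"location": "A", "year": 2005, "risk_scalar": 0.0, "ldi": 0.0},
            {"location": "A", "year": 2006, "risk_scalar": 1.0, "ldi": 0.0},
        ])
        cubes = predict(fitted, table, [(50.0, 60.0)], n_draws=20,
                        m_background=np.full(100, 0.01))
        inc = cubes["incidence"]
        lo = inc.select(year=2005).values[0]
        hi = inc.select(year=2006).values[0]
        beta = fitted.draws[:20, fitted.problem.idx_risk]
        # per draw: a positive coefficient raises incidence with the scalar
        assert np.all((hi >= lo) == (beta >= 0.0))

    def test_draw_mean_close_to_map(self, fitted):
        table = _covariates(locations=("A",))
        cubes = predict(fitted, table, [(60.0, 70.0)],
                        m_background=np.full(100, 0.01))
        vals = cubes["prevalence"].values[0]
        map_pred = predict(fitted, table, [(60.0, 70.0)], n_draws=1,
                           m_background=np.full(100, 0.01))
        # MAP is the first-order centre of the curvature approximation
        mc_se = vals.std() / np.sqrt(len(vals))
        map_val = solve_illness_death(
            RateSet(knots=np.array(KNOTS, float), i=fitted.rate_set().i,
                    r=np.zeros(len(KNOTS)), f=fitted.rate_set().f,
                    m=np.full(len(KNOTS), 0.01)), n_substeps=2)
        mask = (map_val.ages >= 60) & (map_val.ages < 70)
        centre = float(map_val.p[mask].mean())
        assert abs(vals.mean() - centre) < max(3 * mc_se, 0.02 * centre)

    def test_income_coefficient_nonpositive_in_every_draw(self, fitted):
        assert np.all(fitted.draws[:, fitted.problem.idx_income] <= 0.0)

    def test_missing_covariate_aborts(self, fitted):
        with pytest.raises(ValueError, match="risk_scalar"):
            predict(fitted, pd.DataFrame([{"location": "A", "year": 2005,
                                           "ldi": 0.0}]), [(50.0, 60.0)])


class TestCoverage:
    def test_posterior_intervals_cover_truth(self):
        """95% intervals for prevalence contain truth in 90-99% of simulated
        datasets (band accounts for curvature-approximation error)."""
        knots = (0, 40)
        true = RateSet(knots=np.array(knots, float), i=[0.006, 0.015],
                       r=[0.0, 0.0], f=[0.01, 0.025], m=[0.01, 0.01])
        bands = [(0, 20), (20, 40), (40, 60), (60, 80)]
        cfg = DismodConfig(knots=knots, age_max=80, n_substeps=1,
                           remission="zero", maxiter=80, max_newton=25,
                           smoothness_sd={"i": 3.0, "r": 3.0, "f": 3.0})
        check_band = (40.0, 60.0)
        sol = solve_illness_death(true, age_max=80, n_substeps=2)
        mask = (sol.ages >= check_band[0]) & (sol.ages < check_band[1])
        truth_p = float(sol.p[mask].mean())
        rng = np.random.default_rng(2015)
        n_sets, hits = 200, 0
        for _ in range(n_sets):
            data = _simulate_dataset(true, bands, se_frac=0.05, rng=rng,
                                     age_max=80)
            fit = fit_consistent(data, _covariates(), np.full(80, 0.01),
                                 config=cfg, n_draws=300, seed=17)
            cubes = predict(fit, _covariates(), [check_band],
                            m_background=np.full(80, 0.01))
            draws = np.sort(cubes["prevalence"].values[0])
            lo, hi = draws[7], draws[292]  # 2.5% / 97.5% of 300
            hits += lo <= truth_p <= hi
        assert 0.90 * n_sets <= hits <= 0.99 * n_sets
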