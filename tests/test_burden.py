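"""Draw-level DALY accounting and uncertainty machinery."""

import numpy as np
import pandas as pd
import pytest

from respburden.burden import (
    DrawCube,
    age_standardise,
    compute_daly,
    compute_yld,
    compute_yll,
    load_lifetable,
    load_standard_population,
    percent_change,
    summarise,
)
from respburden.published import data_path


def _cube(values, **key_arrays):
    values = np.asarray(values, dtype=float)
    if not key_arrays:
        key_arrays = {"cell": np.arange(values.shape[0])}
    return DrawCube(pd.DataFrame(key_arrays), values)


class TestSummarise:
    def test_ui_of_1_to_1000(self):
        mean, lo, hi = summarise(np.arange(1, 1001))
        assert (lo, hi) == (25.0, 975.0)
        assert mean == pytest.approx(500.5)

    def test_constant_draws(self):
        assert summarise(np.full(1000, 3.7)) == pytest.approx((3.7, 3.7, 3.7))

    def test_matches_quantiles_within_one_order_statistic(self, rng):
        for _ in range(100):
            draws = rng.normal(size=rng.integers(100, 2000))
            _, lo, hi = summarise(draws)
            srt = np.sort(draws)
            q_lo, q_hi = np.quantile(draws, [0.025, 0.975])
            step = 1
            i_lo = np.searchsorted(srt, lo)
            i_hi = np.searchsorted(srt, hi)
            j_lo = np.searchsorted(srt, q_lo)
            j_hi = np.searchsorted(srt, q_hi)
            assert abs(i_lo - j_lo) <= step + 1
            assert abs(i_hi - j_hi) <= step + 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarise(np.array([]))

    def test_interval_contains_mean_for_unimodal_draws(self, rng):
        for _ in range(20):
            draws = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), 1000)
            mean, lo, hi = summarise(draws)
            assert lo <= mean <= hi


class TestPercentChange:
    def test_constant_increase_significant(self):
        mean, lo, hi, sig = percent_change(np.full(100, 100.0),
                                           np.full(100, 150.0))
        assert mean == pytest.approx(50.0)
        assert sig is True

    def test_null_permutation_not_significant(self, rng):
        v0 = rng.lognormal(0, 0.2, 1000)
        v1 = rng.permutation(v0)
        mean, _, _, sig = percent_change(v0, v1)
        assert abs(mean) < 5.0
        assert sig is False

    def test_exactly_95_percent_positive_not_significant(self):
        # strict inequality at the boundary: 95.0% positive is NOT enough
        diff_sign = np.concatenate([np.ones(95), -np.ones(5)])
        v0 = np.full(100, 100.0)
        v1 = v0 + diff_sign
        *_, sig = percent_change(v0, v1)
        assert sig is False
        v1_96 = v0 + np.concatenate([np.ones(96), -np.ones(4)])
        *_, sig96 = percent_change(v0, v1_96)
        assert sig96 is True

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            percent_change(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestYLL:
    def test_deaths_times_life_expectancy(self):
        deaths = _cube([[10.0]], age_start=[60.0])
        lt = pd.Series({60.0: 50.0})
        yll = compute_yll(deaths, lt)
        assert yll.values[0, 0] == pytest.approx(500.0)

    def test_zero_deaths_zero_yll(self):
        deaths = _cube([[0.0, 0.0]], age_start=[60.0])
        yll = compute_yll(deaths, pd.Series({60.0: 30.0}))
        assert np.all(yll.values == 0.0)

    def test_monotone_in_deaths(self, rng):
        d1 = rng.uniform(0, 10, (5, 8))
        d2 = d1 + rng.uniform(0, 1, (5, 8))
        ages = np.arange(50.0, 75.0, 5.0)
        lt = pd.Series(np.linspace(40, 20, 5), index=ages)
        y1 = compute_yll(_cube(d1, age_start=ages), lt)
        y2 = compute_yll(_cube(d2, age_start=ages), lt)
        assert np.all(y2.values >= y1.values)

    def test_missing_age_rejected(self):
        deaths = _cube([[1.0]], age_start=[42.0])
        with pytest.raises(ValueError, match="missing ages"):
            compute_yll(deaths, pd.Series({60.0: 30.0}))


class TestYLD:
    def _keys(self):
        return dict(location=["L"], year=[2015], sex=["male"], age_start=[60.0])

    def _pop(self, n=1000.0):
        idx = pd.MultiIndex.from_tuples([("L", 2015, "male", 60.0)])
        return pd.Series([n], index=idx)

    def test_prevalence_times_dw_times_population(self):
        states = {"moderate": _cube([[0.1]], **self._keys())}
        yld = compute_yld(states, {"moderate": 0.2}, self._pop())
        assert yld.values[0, 0] == pytest.approx(20.0)

    def test_asymptomatic_contributes_nothing(self):
        states = {"asymptomatic": _cube([[0.5]], **self._keys())}
        yld = compute_yld(states, {"asymptomatic": 0.0}, self._pop())
        assert np.all(yld.values == 0.0)

    def test_additive_over_states(self, rng):
        keys = self._keys()
        a = _cube(rng.uniform(0, 0.2, (1, 6)), **keys)
        b = _cube(rng.uniform(0, 0.2, (1, 6)), **keys)
        dw = {"a": 0.1, "b": 0.3}
        both = compute_yld({"a": a, "b": b}, dw, self._pop())
        only_a = compute_yld({"a": a}, dw, self._pop())
        only_b = compute_yld({"b": b}, dw, self._pop())
        assert np.allclose(both.values, only_a.values + only_b.values)

    def test_unknown_state_rejected(self):
        states = {"mystery": _cube([[0.1]], **self._keys())}
        with pytest.raises(ValueError, match="mystery"):
            compute_yld(states, {"moderate": 0.2}, self._pop())


class TestDALY:
    def test_published_global_copd_row(self):
        """Summing the published global COPD YLL and YLD point estimates
        reproduces the published DALY count."""
        yll = _cube([[51803.0]])
        yld = _cube([[12047.0]])
        assert compute_daly(yll, yld).values[0, 0] == pytest.approx(63850.0)

    def test_published_global_asthma_row(self):
        assert compute_daly(_cube([[10270.0]]), _cube([[15899.0]])
                            ).values[0, 0] == pytest.approx(26169.0)

    def test_zero_yld_daly_equals_yll(self, rng):
        yll = _cube(rng.uniform(0, 100, (4, 8)))
        daly = compute_daly(yll, _cube(np.zeros((4, 8))))
        assert np.array_equal(daly.values, yll.values)

    def test_identity_per_draw(self, rng):
        yll = _cube(rng.uniform(0, 100, (4, 16)))
        yld = _cube(rng.uniform(0, 100, (4, 16)))
        daly = compute_daly(yll, yld)
        assert np.array_equal(daly.values, yll.values + yld.values)


class TestAgeStandardise:
    def test_constant_rate_unchanged(self):
        ages = np.array([50.0, 60.0, 70.0])
        rates = _cube(np.full((3, 4), 7.0), age_start=ages)
        std = pd.Series([0.5, 0.3, 0.2], index=ages)
        out = age_standardise(rates, std)
        assert np.allclose(out.values, 7.0)

    def test_point_mass_weights(self):
        ages = np.array([50.0, 60.0])
        rates = _cube(np.array([[1.0], [9.0]]), age_start=ages)
        std = pd.Series([0.0, 1.0], index=ages)
        assert age_standardise(rates, std).values[0, 0] == pytest.approx(9.0)

    def test_invariant_to_age_order(self, rng):
        ages = np.array([50.0, 60.0, 70.0])
        vals = rng.uniform(0, 10, (3, 5))
        std = pd.Series(rng.dirichlet(np.ones(3)), index=ages)
        a = age_standardise(_cube(vals, age_start=ages), std)
        perm = [2, 0, 1]
        b = age_standardise(_cube(vals[perm], age_start=ages[perm]), std)
        assert np.allclose(a.values, b.values)

    def test_result_within_age_specific_range(self, rng):
        ages = np.arange(0.0, 100.0, 5.0)
        vals = rng.uniform(0, 100, (len(ages), 10))
        std = pd.Series(rng.dirichlet(np.ones(len(ages))), index=ages)
        out = age_standardise(_cube(vals, age_start=ages), std)
        assert np.all(out.values <= vals.max(axis=0) + 1e-12)
        assert np.all(out.values >= vals.min(axis=0) - 1e-12)

    def test_missing_age_rejected(self):
        rates = _cube([[1.0]], age_start=[50.0])
        std = pd.Series([0.5, 0.5], index=[50.0, 60.0])
        with pytest.raises(ValueError, match="missing standard ages"):
            age_standardise(rates, std)


class TestFixtureTables:
    def test_lifetable_valid(self):
        lt = load_lifetable(data_path("standard_lifetable.csv"))
        assert (lt > 0).all()
        assert (np.diff(lt.to_numpy()) <= 0).all()

    def test_standard_population_normalised(self):
        sp = load_standard_population(data_path("standard_population.csv"))
        assert sp.sum() == pytest.approx(1.0)
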