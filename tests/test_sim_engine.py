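"""Simulation engine: sampling families, pairing logic, catalog, determinism."""

import math

import numpy as np
import pytest

from medsurv import (
    ConfigurationError,
    GroupSpec,
    ScenarioSpec,
    generate_grouped_data,
    run_simulation,
    sample_censoring,
    sample_survival,
    scenario_catalog,
)
from medsurv.sim_engine import catalog_keys, CENSOR_RATES, LARGE_N, SMALL_N


class TestSampleSurvival:
    def test_uniform_support(self, rng):
        g = GroupSpec("uniform", theta=10.0, a=4.0, c=2.0, n=5000)
        x = sample_survival(g, rng)
        assert x.min() > 8.0 and x.max() < 12.0

    def test_exponential_shift_and_median(self, rng):
        g = GroupSpec("exponential", theta=10.0, a=0.1, n=100_000)
        x = sample_survival(g, rng)
        assert x.min() >= 10.0
        # median of theta + Exp(rate a) is theta + log(2)/a
        assert np.median(x) == pytest.approx(10 + math.log(2) / 0.1, rel=0.02)

    def test_lognormal_population_median(self, rng):
        g = GroupSpec("lognormal", theta=math.log(10.0), a=0.3, n=100_000)
        x = sample_survival(g, rng)
        assert np.median(x) == pytest.approx(10.0, rel=0.02)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError, match="family"):
            GroupSpec("weibull", theta=1.0, a=1.0, n=10)


class TestSampleCensoring:
    def test_no_censoring_at_rate_zero(self, rng):
        g = GroupSpec("exponential", theta=0.0, a=1.0, n=100)
        y = sample_censoring(g, 0.0, rng)
        assert np.all(np.isinf(y))

    def test_uniform_support(self, rng):
        g = GroupSpec("uniform", theta=10.0, a=4.0, c=2.0, n=5000)
        p = 0.2
        y = sample_censoring(g, p, rng)
        assert y.min() > 10 - 2.0
        assert y.max() < 10 + 2.0 + (1 - 2 * p) / p

    @pytest.mark.parametrize("p", [0.1, 0.2, 0.3])
    def test_exponential_censored_fraction_is_exactly_p(self, rng, p):
        # competing exponentials: P(censor) = rate_c/(rate_x + rate_c) = p
        g = GroupSpec("exponential", theta=10.0, a=0.1, n=100_000)
        x = sample_survival(g, rng)
        y = sample_censoring(g, p, rng)
        frac = np.mean(y < x)
        assert frac == pytest.approx(p, abs=3 * math.sqrt(p * (1 - p) / g.n))

    def test_invalid_rate_rejected(self, rng):
        g = GroupSpec("exponential", theta=0.0, a=1.0, n=10)
        with pytest.raises(ConfigurationError):
            sample_censoring(g, 1.0, rng)


class TestGenerateGroupedData:
    def test_no_censoring_all_events(self, rng):
        spec = scenario_catalog(4, "exponential", 0.0, reps=1, seed=3)
        data = generate_grouped_data(spec, rng)
        assert all(np.all(g.events == 1) for g in data.groups)
        assert [g.n for g in data.groups] == list(SMALL_N)

    def test_deterministic_for_fixed_seed(self):
        spec = scenario_catalog(4, "uniform", 0.2, reps=1, seed=11)
        d1 = generate_grouped_data(spec, np.random.default_rng(5))
        d2 = generate_grouped_data(spec, np.random.default_rng(5))
        for a, b in zip(d1.groups, d2.groups):
            np.testing.assert_array_equal(a.times, b.times)
            np.testing.assert_array_equal(a.events, b.events)

    def test_event_fraction_tracks_nominal_rate(self, rng):
        groups = (GroupSpec("exponential", theta=0.0, a=0.5, n=20_000),) * 2
        spec = ScenarioSpec(groups=groups, censor_rate=0.3, reps=1, seed=1)
        data = generate_grouped_data(spec, rng)
        for g in data.groups:
            assert np.mean(g.events) == pytest.approx(0.7, abs=0.02)


class TestRunSimulation:
    def test_alpha_one_rejects_everything(self):
        spec = scenario_catalog(4, "uniform", 0.0, alpha=0.999, reps=30, seed=2)
        res = run_simulation(spec)
        # p-values are continuous: p <= 0.999 essentially always
        assert res.rejection["composite"] >= 0.9

    def test_same_seed_reproduces_result(self):
        spec = scenario_catalog(4, "exponential", 0.3, reps=60, seed=42)
        r1 = run_simulation(spec)
        r2 = run_simulation(spec)
        assert r1.rejection == r2.rejection
        assert r1.degenerate_count == r2.degenerate_count

    def test_greenwood_only_rejects_at_least_as_often(self):
        # statistic ordering implies nested rejection regions per replicate
        spec = scenario_catalog(4, "lognormal", 0.2, reps=300, seed=7)
        res = run_simulation(spec, tests=("composite", "greenwood_only"))
        assert res.rejection["greenwood_only"] >= res.rejection["composite"]

    def test_rejection_monotone_in_alpha(self):
        rejs = []
        for alpha in (0.01, 0.05, 0.2):
            spec = scenario_catalog(
                4, "exponential", 0.1, alpha=alpha, reps=200, seed=9
            )
            rejs.append(run_simulation(spec).rejection["composite"])
        assert rejs == sorted(rejs)

    def test_power_scenario_beats_size(self):
        # unequal-median cell: rejection well above the 0.05 level
        spec = scenario_catalog(6, "exponential", 0.0, reps=300, seed=13)
        res = run_simulation(spec, tests=("composite",))
        assert res.rejection["composite"] > 0.10

    def test_unknown_variant_rejected(self):
        spec = scenario_catalog(4, "uniform", 0.0, reps=5, seed=1)
        with pytest.raises(ConfigurationError, match="variant"):
            run_simulation(spec, tests=("bootstrap",))

    def test_records_are_serializable(self):
        spec = scenario_catalog(4, "uniform", 0.1, reps=40, seed=3)
        recs = run_simulation(spec).to_records()
        assert {r["variant"] for r in recs} == {"composite", "greenwood_only"}
        for r in recs:
            assert 0.0 <= r["rejection"] <= 1.0
            assert r["reps"] == 40


class TestScenarioCatalog:
    def test_table1_exponential_row(self):
        spec = scenario_catalog(1, "exponential", 0.0)
        assert [g.family for g in spec.groups] == ["exponential"] * 4
        assert [g.theta for g in spec.groups] == [10.0] * 4
        assert [g.a for g in spec.groups] == [0.1] * 4
        assert [g.n for g in spec.groups] == list(LARGE_N)

    def test_table5_lognormal_row(self):
        spec = scenario_catalog(5, "lognormal", 0.1)
        assert [g.a for g in spec.groups] == [0.2, 0.3, 0.4, 0.5]
        assert [g.n for g in spec.groups] == list(SMALL_N)

    def test_table6_mixed_row(self):
        spec = scenario_catalog(6, "uniform_exponential", 0.0)
        fams = [g.family for g in spec.groups]
        assert fams == ["uniform", "uniform", "exponential", "exponential"]
        thetas = [g.theta for g in spec.groups]
        assert thetas[0] == 10.0 and thetas[1] == 13.0
        assert thetas[2] == pytest.approx(13 - 10 * math.log(2))
        assert thetas[3] == pytest.approx(10 - 10 * math.log(2))
        assert spec.groups[0].c == 0.01

    def test_null_rows_have_equal_population_medians(self):
        # every table-2/5 row is a null scenario: medians all equal
        for row in catalog_keys()[2]:
            spec = scenario_catalog(2, row, 0.0)
            medians = []
            for g in spec.groups:
                if g.family == "uniform":
                    medians.append(g.theta)
                elif g.family == "exponential":
                    medians.append(g.theta + math.log(2) / g.a)
                else:
                    medians.append(math.exp(g.theta))
            assert medians == pytest.approx([medians[0]] * 4, rel=1e-12)

    def test_unknown_keys_listed_in_error(self):
        with pytest.raises(ConfigurationError, match="valid tables"):
            scenario_catalog(9, "uniform", 0.0)
        with pytest.raises(ConfigurationError, match="valid rows"):
            scenario_catalog(1, "weibull", 0.0)
        with pytest.raises(ConfigurationError, match="valid rates"):
            scenario_catalog(1, "uniform", 0.15)

    def test_catalog_covers_all_cells(self):
        keys = catalog_keys()
        assert set(keys) == {1, 2, 3, 4, 5, 6}
        assert len(keys[2]) == len(keys[5]) == 6
        for t in keys:
            for row in keys[t]:
                for p in CENSOR_RATES:
                    scenario_catalog(t, row, p)  # must not raise
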