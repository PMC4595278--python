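import numpy as np
import pytest

from racert.binning import fine_boundaries
from racert.mc_test import test_equality as run_observer_test
from racert.mc_test import test_equality_samples as run_test
from racert.mc_test import (
    TestConfig,
    group_level_decision,
    p_value_from_distances,
    run_parameter_sweep,
    simulate_null_dataset,
    sweep_breaking_counts,
    sweep_observer_fractions,
)
from racert.null_model import NullDistributions, fine_counts, fit_null_distributions
from racert.race_algebra import equality_catalog
from racert.rt_io import split_by_scene_color
from racert.synthetic_observer import generate_dataset, scenario_preset

CAT = equality_catalog()


class TestPValue:
    def test_strictly_greater_fraction(self):
        sims = np.array([0.1, 0.2, 0.3, 0.4])
        assert p_value_from_distances(0.25, sims) == (0.5, False)
        # ties do not count as larger
        assert p_value_from_distances(0.3, sims) == (0.25, False)

    def test_zero_exceedance_reports_bound(self):
        sims = np.linspace(0.0, 0.9, 500)
        p, bound = p_value_from_distances(1.0, sims)
        assert p == 1.0 / 500 and bound


class TestSimulateNull:
    def _null(self, L=10):
        eq = CAT["RE2"]
        rng = np.random.default_rng(0)
        dists = {t: rng.dirichlet(np.ones(L)) for t in eq.side2}
        from racert.race_algebra import race_of_binned

        dists[eq.goal] = race_of_binned(list(dists.values()))
        return NullDistributions(eq, dists, 0.0, 0.0)

    def test_point_mass_stays_in_its_bin(self):
        eq = CAT["RE2"]
        edges = np.linspace(0.3, 1.3, 11)
        dists = {t: np.eye(10)[4] for t in eq.all_types}
        null = NullDistributions(eq, dists, 0.0, 0.0)
        out = simulate_null_dataset(null, {t: 50 for t in eq.all_types}, edges,
                                    np.random.default_rng(1))
        for s in out.values():
            assert np.all((s >= edges[4]) & (s < edges[5]))

    def test_empirical_frequencies_match_multinomial_bounds(self):
        null = self._null()
        edges = np.linspace(0.3, 1.3, 11)
        n = 100_000
        out = simulate_null_dataset(null, {t: n for t in null.dists}, edges,
                                    np.random.default_rng(2))
        for t, p in null.dists.items():
            idx = np.searchsorted(edges, out[t], side="right") - 1
            freq = np.bincount(idx, minlength=10) / n
            bound = 4 * np.sqrt(p * (1 - p) / n) + 1e-9
            assert np.all(np.abs(freq - p) <= bound)

    def test_same_seed_gives_identical_samples(self):
        null = self._null()
        edges = np.linspace(0.3, 1.3, 11)
        counts = {t: 20 for t in null.dists}
        a = simulate_null_dataset(null, counts, edges, np.random.default_rng(3))
        b = simulate_null_dataset(null, counts, edges, np.random.default_rng(3))
        for t in counts:
            assert np.array_equal(a[t], b[t])


class TestGroupDecision:
    def test_thresholds_match_binomial_argument(self):
        # 6 observers: two breakers suffice; 8 observers need three
        assert group_level_decision([False] * 6).threshold == 2
        assert group_level_decision([False] * 8).threshold == 3

    def test_hand_computed_tail_probabilities(self):
        d = group_level_decision([True, True] + [False] * 4)
        assert d.broken
        expected = 1 - 0.95**6 - 6 * 0.05 * 0.95**5
        assert d.chance_probability == pytest.approx(expected)
        d = group_level_decision([False] * 6)
        assert not d.broken and d.chance_probability == 1.0
        d = group_level_decision([True, True] + [False] * 6)
        assert not d.broken  # 2 of 8 is not enough


class TestFullPipeline:
    def test_reproducible_given_seed(self, re2_null_samples):
        config = TestConfig(m=30, L=20)
        a = run_test(re2_null_samples, CAT["RE2"], config,
                                  np.random.default_rng(42))
        b = run_test(re2_null_samples, CAT["RE2"], config,
                                  np.random.default_rng(42))
        assert a.p_value == b.p_value
        assert np.array_equal(a.d_simulated, b.d_simulated)

    def test_warns_on_small_samples(self):
        rng = np.random.default_rng(4)
        samples = {t: rng.uniform(0.4, 0.9, 20) for t in CAT["RE2"].all_types}
        with pytest.warns(UserWarning, match="only 20 samples"):
            run_test(samples, CAT["RE2"], TestConfig(m=5, L=10), rng)

    def test_dataset_wrapper_uses_scene_pool(self):
        ds = generate_dataset(scenario_preset("no_conjunction"), n_per_type=80,
                              observers=1, seed=6)
        res = run_observer_test(ds, "S01", "purple", CAT["RE2"],
                            TestConfig(m=20, L=15), np.random.default_rng(0))
        assert res.observer_id == "S01" and res.scene_color == "purple"
        assert 0 < res.p_value <= 1

    def test_rejects_strong_conjunction_observer(self, v1_like_model):
        from conftest import rt_samples

        samples = rt_samples(v1_like_model, CAT["RE2"].all_types, 300, seed=13)
        res = run_test(samples, CAT["RE2"], TestConfig(m=100, L=20),
                                    np.random.default_rng(5))
        assert res.rejected


class TestSweep:
    def test_simple_equality_runs_80_configs(self, re2_null_samples):
        sweep = run_parameter_sweep({"S01": re2_null_samples}, CAT["RE2"],
                                    master_seed=1, m=5, L=15)
        assert len(sweep) == 80
        assert sweep["config_index"].nunique() == 80
        assert set(sweep["N"]) == {8, 9, 10, 11, 12}
        assert sweep["error"].eq("").all()
        frac = sweep_observer_fractions(sweep)
        assert 0.0 <= frac.loc["S01"] <= 1.0
        mean, sd, counts = sweep_breaking_counts(sweep)
        assert len(counts) == 80

    def test_complex_equality_enumerates_320_configs(self, no_conjunction_model):
        from conftest import rt_samples

        samples = rt_samples(no_conjunction_model, CAT["RE1"].all_types, 60, seed=17)
        sweep = run_parameter_sweep({"S01": samples}, CAT["RE1"],
                                    master_seed=2, m=2, L=12)
        assert len(sweep) == 320
        assert sweep["objective_metric"].nunique() == 4

    def test_order_independent_seeds(self, re2_null_samples):
        a = run_parameter_sweep({"S01": re2_null_samples}, CAT["RE2"],
                                master_seed=3, m=4, L=15)
        b = run_parameter_sweep({"S01": re2_null_samples}, CAT["RE2"],
                                master_seed=3, m=4, L=15)
        assert a["p_value"].equals(b["p_value"])
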