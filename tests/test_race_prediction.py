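import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from racert.binning import discretize
from racert.race_algebra import equality_catalog, forward_race, winner_samples
from racert.race_prediction import (
    KL_EPSILON,
    METRICS,
    distance,
    predict_goal,
    predict_goal_constrained,
    predict_goal_direct,
    solve_goal_distribution,
)

CAT = equality_catalog()


class TestDistance:
    def test_identity_is_zero_for_all_metrics(self):
        p = np.array([0.2, 0.3, 0.5])
        for m in METRICS:
            assert distance(p, p, m) == pytest.approx(0.0, abs=1e-15)

    def test_hand_values_on_disjoint_point_masses(self):
        P, Q = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert distance(P, Q, "sq_hamming") == pytest.approx(2.0)
        assert distance(P, Q, "l1") == pytest.approx(2.0)
        assert distance(P, Q, "hellinger") == pytest.approx(2.0)
        assert distance(P, Q, "hellinger_literal") == pytest.approx(2.0)

    def test_kl_like_guard_keeps_zero_bins_finite(self):
        P, Q = np.array([1.0, 0.0]), np.array([1.0, 0.0])
        assert distance(P, Q, "kl_like") == pytest.approx(0.0, abs=1e-12)
        P = np.array([0.5, 0.5])
        d = distance(P, Q, "kl_like")
        assert np.isfinite(d)
        assert KL_EPSILON < 1e-100

    def test_symmetry_and_asymmetry(self):
        rng = np.random.default_rng(0)
        P, Q = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        for m in ("sq_hamming", "hellinger", "l1"):
            assert distance(P, Q, m) == pytest.approx(distance(Q, P, m))
        assert distance(P, Q, "kl_like") != pytest.approx(distance(Q, P, "kl_like"))

    def test_errors(self):
        with pytest.raises(ValueError):
            distance(np.array([1.0]), np.array([0.5, 0.5]), "l1")
        with pytest.raises(ValueError):
            distance(np.array([1.0]), np.array([1.0]), "mahalanobis")


class TestSolve:
    def test_round_trip_exact(self):
        rng = np.random.default_rng(1)
        for n in (2, 5, 9, 12):
            for _ in range(20):
                p = rng.dirichlet(np.ones(n))
                q = rng.dirichlet(np.ones(n))
                Q = forward_race(p, q).probs
                sol = solve_goal_distribution(q, Q)
                assert sol.feasible
                assert np.allclose(sol.p, p, atol=1e-12)

    def test_hand_case_and_infeasible(self):
        sol = solve_goal_distribution(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert sol.feasible and np.allclose(sol.p, [1.0, 0.0])
        # q already puts more early mass than Q allows: p_1 must go negative
        sol = solve_goal_distribution(np.array([0.9, 0.1]), np.array([0.1, 0.9]))
        assert not sol.feasible
        assert 0 in sol.violations
        assert sol.p[0] == pytest.approx((0.1 - 0.9) / (1 - 0.9))


class TestDirectPrediction:
    def test_point_mass_racers(self):
        edges = np.array([0.3, 0.55, 0.8])
        samples = {"C": np.array([0.5]), "O": np.array([0.6]), "CO": np.array([0.5])}
        res = predict_goal_direct(CAT["RE2"], samples, edges)
        assert res.feasible_direct and res.residual == 0.0
        assert np.allclose(res.predicted.probs, [1.0, 0.0])

    def test_re5_matches_enumerated_minima(self):
        rng = np.random.default_rng(2)
        samples = {t: rng.uniform(0.35, 0.95, 10) for t in ("C", "M", "O")}
        edges = np.array([0.3, 0.5, 0.7, 1.0])
        res = predict_goal_direct(CAT["RE5"], samples, edges)
        ws = winner_samples([samples[t] for t in ("C", "M", "O")]).values
        assert ws.size == 1000
        assert np.allclose(res.predicted.probs, discretize(ws, edges).probs,
                           atol=1e-12)

    def test_wrong_equality_label_raises(self):
        with pytest.raises(ValueError):
            predict_goal_direct(CAT["RE1"], {}, np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            predict_goal_constrained(CAT["RE2"], {}, np.array([0.0, 1.0]))


class TestConstrainedPrediction:
    def test_constrained_matches_grid_search(self):
        # q front-loads mass so the algebraic solution leaves the simplex
        q = np.array([0.5, 0.5])
        Q = np.array([0.2, 0.8])
        assert not solve_goal_distribution(q, Q).feasible
        for metric in ("l1", "sq_hamming", "hellinger", "kl_like"):
            grid = np.linspace(0.0, 1.0, 1001)
            vals = [
                distance(forward_race(np.array([g, 1 - g]), q).probs, Q, metric)
                for g in grid
            ]
            best = grid[int(np.argmin(vals))]
            res = _constrained_re1(q, Q, metric)
            assert res.residual <= min(vals) + 1e-9
            assert abs(res.predicted.probs[0] - best) <= 2e-3

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        samples = {t: rng.uniform(0.35, 0.95, 40) for t in CAT["RE2"].all_types}
        edges = np.array([0.3, 0.5, 0.7, 1.0])
        a = predict_goal(CAT["RE2"], samples, edges)
        shuffled = {t: rng.permutation(s) for t, s in samples.items()}
        b = predict_goal(CAT["RE2"], shuffled, edges)
        assert np.allclose(a.predicted.probs, b.predicted.probs)


def _constrained_re1(q, Q, metric):
    """Drive the constrained optimizer directly on crafted (q, Q) by faking
    point-mass racer samples that bin to them exactly."""
    from racert.race_prediction import PredictionResult, _minimize_on_simplex

    def objective(x):
        x = np.clip(x, 0.0, None)
        s = x.sum()
        return distance(forward_race(x / s, q).probs, Q, metric) if s > 0 else np.inf

    rng = np.random.default_rng(0)
    starts = [np.array([0.5, 0.5])] + [rng.dirichlet(np.ones(2)) for _ in range(5)]
    p, resid = _minimize_on_simplex(objective, 2, starts)
    from racert.binning import BinnedDist

    return PredictionResult(BinnedDist(probs=p), False, metric, resid)


def test_constrained_feasible_on_equality_satisfying_data(no_conjunction_model):
    """Data generated with no conjunction cells satisfy the non-spurious
    equality, so the direct linear solve should usually be admissible."""
    from conftest import rt_samples

    eq = CAT["RE1"]
    samples = rt_samples(no_conjunction_model, eq.all_types, 400, seed=21)
    pooled = np.concatenate(list(samples.values()))
    from racert.binning import coarse_boundaries, fine_boundaries

    fine = fine_boundaries(pooled, 60)
    coarse = coarse_boundaries(fine, samples["CMO"], pooled.min(), pooled.max(),
                               9, "erf:1.35")
    res = predict_goal_constrained(eq, samples, coarse)
    assert res.predicted.probs == pytest.approx(res.predicted.probs)
    assert res.residual < 0.05
    # the prediction should resemble the observed goal distribution
    obs = discretize(samples["CMO"], coarse).probs
    assert distance(obs, res.predicted.probs, "l1") < 0.35
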