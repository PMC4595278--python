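"""Monte-Carlo hypothesis test of a race equality, the group-level binomial
criterion and the technical-parameter sweep.

A race equality is a null hypothesis.  The observed distance D between the
predicted and observed goal distributions is compared with m distances
obtained by re-running the identical prediction pipeline on datasets drawn
from the constrained-MLE null distributions (which satisfy the equality
exactly while resembling the data).  The p value is the fraction of simulated
distances strictly exceeding the observed one, floored at 1/m; the equality
is declared broken when p < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import binom

from .binning import coarse_boundaries, discretize, fine_boundaries
from .null_model import NullDistributions, fine_counts, fit_null_distributions
from .race_algebra import RaceEquality, winner_minmax
from .race_prediction import distance, predict_goal
from .rt_io import RTDataset

__all__ = [
    "TestConfig",
    "TestResult",
    "GroupDecision",
    "SWEEP_N_VALUES",
    "SWEEP_F_SCHEMES",
    "SWEEP_METRICS",
    "p_value_from_distances",
    "simulate_null_dataset",
    "observed_distance",
    "test_equality_samples",
    "test_equality",
    "group_level_decision",
    "run_parameter_sweep",
    "sweep_observer_fractions",
    "sweep_breaking_counts",
]

SWEEP_N_VALUES = (8, 9, 10, 11, 12)
SWEEP_F_SCHEMES = ("uniform", "erf:1.25", "erf:1.35", "erf:1.45")
SWEEP_METRICS = ("sq_hamming", "hellinger", "l1", "kl_like")


@dataclass(frozen=True)
class TestConfig:
    """Technical parameters of one race-equality test."""

    __test__ = False  # not a pytest class, despite the name

    N: int = 9
    f_scheme: str = "erf:1.35"
    d_metric: str = "kl_like"
    objective_metric: str = "kl_like"
    m: int = 500
    alpha: float = 0.05
    L: int = 100


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    d_observed: float
    d_simulated: np.ndarray
    p_value: float
    p_is_bound: bool
    rejected: bool
    config: TestConfig
    equality_label: str
    observer_id: str | None = None
    scene_color: str | None = None


@dataclass(frozen=True)
class GroupDecision:
    broken: bool
    chance_probability: float
    breakers: int
    n_observers: int
    threshold: int


def p_value_from_distances(
    d_observed: float, d_simulated: np.ndarray
) -> tuple[float, bool]:
    """Fraction of simulated distances strictly larger than the observed one;
    when that fraction is zero the bound p = 1/m is reported instead."""
    d_simulated = np.asarray(d_simulated, dtype=float)
    m = d_simulated.size
    if m == 0:
        raise ValueError("need at least one simulated distance")
    exceed = int(np.sum(d_simulated > d_observed))
    if exceed == 0:
        return 1.0 / m, True
    return exceed / m, False


def simulate_null_dataset(
    null: NullDistributions,
    sample_counts: dict[str, int],
    fine_edges: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw per-type RT samples from the null distributions: a fine bin from
    p̂_α, then a uniform position inside the half-open bin."""
    T = np.asarray(fine_edges, dtype=float)
    widths = np.diff(T)
    out: dict[str, np.ndarray] = {}
    for t, p in null.dists.items():
        n = int(sample_counts[t])
        if n <= 0:
            raise ValueError(f"type {t} has zero requested samples")
        p = np.clip(np.asarray(p, dtype=float), 0.0, None)
        idx = rng.choice(p.size, size=n, p=p / p.sum())
        out[t] = T[idx] + rng.random(n) * widths[idx]
    return out


def observed_distance(
    samples: dict[str, np.ndarray],
    equality: RaceEquality,
    fine_edges: np.ndarray,
    config: TestConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """One pass of the prediction pipeline: coarse boundaries from these
    samples (fine boundaries held fixed), goal prediction, and the distance
    between observed and predicted goal distributions."""
    goal = samples[equality.goal]
    lo, hi = winner_minmax([samples[t] for t in equality.side2])
    pool_min = min(float(goal.min()), lo)
    pool_max = max(float(goal.max()), hi)
    if equality.is_complex:
        plo, phi = winner_minmax([samples[t] for t in equality.part_types])
        pool_min, pool_max = min(pool_min, plo), max(pool_max, phi)
    coarse = coarse_boundaries(
        fine_edges, goal, pool_min, pool_max, config.N, config.f_scheme
    )
    pred = predict_goal(equality, samples, coarse, config.objective_metric, rng)
    observed = discretize(goal, coarse)
    return distance(observed, pred.predicted, config.d_metric)


def test_equality_samples(
    samples: dict[str, np.ndarray],
    equality: RaceEquality,
    config: TestConfig = TestConfig(),
    rng: np.random.Generator | None = None,
    null: NullDistributions | None = None,
    observer_id: str | None = None,
    scene_color: str | None = None,
) -> TestResult:
    """Full Monte-Carlo test of one race equality on per-type RT samples.

    A precomputed ``null`` (which depends only on the data, the equality and
    L — not on N, the fraction scheme or the metrics) may be passed to avoid
    refitting, e.g. across sweep configurations.
    """
    rng = rng or np.random.default_rng()
    for t in equality.all_types:
        if t not in samples or len(samples[t]) == 0:
            raise ValueError(f"no samples for type {t}")
        if len(samples[t]) < 30:
            warnings.warn(
                f"type {t} has only {len(samples[t])} samples; the test may be "
                "unstable",
                stacklevel=2,
            )
    pooled = np.concatenate([samples[t] for t in equality.all_types])
    fine = fine_boundaries(pooled, config.L)
    d_obs = observed_distance(samples, equality, fine, config, rng)
    if null is None:
        null = fit_null_distributions(fine_counts(
            {t: samples[t] for t in equality.all_types}, fine
        ), equality)
    counts = {t: len(samples[t]) for t in equality.all_types}
    d_sim = np.empty(config.m)
    for s in range(config.m):
        sim = simulate_null_dataset(null, counts, fine, rng)
        d_sim[s] = observed_distance(sim, equality, fine, config, rng)
    p, bound = p_value_from_distances(d_obs, d_sim)
    return TestResult(
        d_observed=d_obs,
        d_simulated=d_sim,
        p_value=p,
        p_is_bound=bound,
        rejected=p < config.alpha,
        config=config,
        equality_label=equality.label,
        observer_id=observer_id,
        scene_color=scene_color,
    )


def test_equality(
    data: RTDataset,
    observer_id: str,
    scene_color: str,
    equality: RaceEquality,
    config: TestConfig = TestConfig(),
    rng: np.random.Generator | None = None,
    null: NullDistributions | None = None,
) -> TestResult:
    """Run the test on one observer's scene-color pool of a filtered dataset."""
    samples = data.sample_map(observer_id, equality.all_types, scene_color)
    return test_equality_samples(
        samples, equality, config, rng, null,
        observer_id=observer_id, scene_color=scene_color,
    )


def group_level_decision(
    rejections: list[bool] | list[TestResult], alpha: float = 0.05
) -> GroupDecision:
    """Binomial group criterion across observers.

    With per-observer false-rejection probability alpha, the chance that at
    least k of n observers break a true equality is the binomial upper tail;
    the equality is declared broken at the smallest k whose tail probability
    falls below alpha (k = 2 for n = 6 and k = 3 for n = 8).
    """
    flags = [r.rejected if isinstance(r, TestResult) else bool(r) for r in rejections]
    n = len(flags)
    if n == 0:
        raise ValueError("need at least one observer result")
    breakers = int(sum(flags))
    threshold = next(
        k for k in range(1, n + 2) if binom.sf(k - 1, n, alpha) < alpha
    )
    chance = float(binom.sf(breakers - 1, n, alpha)) if breakers > 0 else 1.0
    return GroupDecision(
        broken=breakers >= threshold,
        chance_probability=chance,
        breakers=breakers,
        n_observers=n,
        threshold=threshold,
    )


def run_parameter_sweep(
    samples_by_observer: dict[str, dict[str, np.ndarray]],
    equality: RaceEquality,
    master_seed: int = 0,
    m: int = 500,
    L: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test one equality under every technical-parameter combination.

    5 N values x 4 boundary schemes x 4 distance metrics (x 4 objective
    metrics for the complex equalities) = 80 or 320 configurations, each run
    on every observer with a seed derived from the master seed and the
    configuration index, so results are independent of execution order.
    Failures of individual configurations are recorded and the sweep
    continues.  The null fit is computed once per observer and reused.
    """
    objectives = SWEEP_METRICS if equality.is_complex else (None,)
    combos = list(product(SWEEP_N_VALUES, SWEEP_F_SCHEMES, SWEEP_METRICS, objectives))

    nulls: dict[str, NullDistributions] = {}
    fines: dict[str, np.ndarray] = {}
    for obs, samples in samples_by_observer.items():
        pooled = np.concatenate([samples[t] for t in equality.all_types])
        fines[obs] = fine_boundaries(pooled, L)
        nulls[obs] = fit_null_distributions(
            fine_counts({t: samples[t] for t in equality.all_types}, fines[obs]),
            equality,
        )

    rows = []
    for ci, (N, fs, dm, om) in enumerate(combos):
        config = TestConfig(
            N=N, f_scheme=fs, d_metric=dm,
            objective_metric=om if om is not None else "kl_like",
            m=m, alpha=alpha, L=L,
        )
        for oi, (obs, samples) in enumerate(samples_by_observer.items()):
            rng = np.random.default_rng(
                np.random.SeedSequence(master_seed, spawn_key=(ci, oi))
            )
            row = {
                "config_index": ci, "N": N, "f_scheme": fs, "d_metric": dm,
                "objective_metric": om, "observer_id": obs,
            }
            try:
                res = test_equality_samples(
                    samples, equality, config, rng, null=nulls[obs],
                    observer_id=obs,
                )
                row.update(
                    p_value=res.p_value, rejected=res.rejected,
                    d_observed=res.d_observed, error="",
                )
            except Exception as exc:  # keep sweeping past bad configurations
                row.update(p_value=np.nan, rejected=None, d_observed=np.nan,
                           error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def sweep_observer_fractions(sweep: pd.DataFrame) -> pd.Series:
    """Per-observer fraction of sweep configurations that falsify the
    equality."""
    ok = sweep[sweep["error"] == ""]
    return ok.groupby("observer_id")["rejected"].mean()


def sweep_breaking_counts(sweep: pd.DataFrame) -> tuple[float, float, pd.Series]:
    """Observers broken per configuration: (mean, SD, per-config counts)."""
    ok = sweep[sweep["error"] == ""]
    counts = ok.groupby("config_index")["rejected"].sum()
    return float(counts.mean()), float(counts.std(ddof=1)), counts
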