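"""Predicting the goal RT distribution from a race equality, and distances
between binned distributions.

For the simple equalities (RE2-RE5) the goal type stands alone on side 1, so
its predicted distribution is just the binned race-winner distribution of the
side-2 racers.  For the complex equalities (RE1, RE6-RE8) the goal races
against a partial racer set on its own side: writing q for the binned
partial-race winner and Q for the binned side-2 winner, the goal distribution
p solves the lower-triangular system

    p_i (1 - Σ_{j<=i} q_j) + q_i (1 - Σ_{j<=i} p_j) + p_i q_i = Q_i.

When the algebraic solution leaves the probability simplex (sampling noise,
or a false equality), p is instead chosen to minimize a distance between the
raced side-1 distribution and Q over the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .binning import BinnedDist
from .race_algebra import RaceEquality, forward_race, winner_distribution

__all__ = [
    "METRICS",
    "KL_EPSILON",
    "distance",
    "SolveResult",
    "solve_goal_distribution",
    "PredictionResult",
    "predict_goal_direct",
    "predict_goal_constrained",
    "predict_goal",
]

METRICS = ("sq_hamming", "hellinger", "hellinger_literal", "l1", "kl_like")

#: guard constant for the KL-like distance; strictly below 1e-100 as the
#: construction requires, and representable in double precision.
KL_EPSILON = 1e-300


def distance(P: np.ndarray | BinnedDist, Q: np.ndarray | BinnedDist, metric: str) -> float:
    """Distance between two binned distributions.

    ``sq_hamming``: Σ (P_i - Q_i)^2.  ``hellinger``: Σ (√P_i - √Q_i)^2
    (``hellinger_literal`` is the square-root-free variant, identical to
    sq_hamming, kept for sensitivity checks).  ``l1``: Σ |P_i - Q_i|.
    ``kl_like``: Σ max(Q_i, ε) log(max(Q_i, ε)/max(P_i, ε)) — the KL
    divergence away from zero bins, finite everywhere thanks to the ε guard.
    """
    p = P.probs if isinstance(P, BinnedDist) else np.asarray(P, dtype=float)
    q = Q.probs if isinstance(Q, BinnedDist) else np.asarray(Q, dtype=float)
    if p.size != q.size:
        raise ValueError("P and Q must have the same number of bins")
    if metric == "sq_hamming" or metric == "hellinger_literal":
        return float(np.sum((p - q) ** 2))
    if metric == "hellinger":
        return float(np.sum((np.sqrt(np.clip(p, 0, None)) - np.sqrt(np.clip(q, 0, None))) ** 2))
    if metric == "l1":
        return float(np.sum(np.abs(p - q)))
    if metric == "kl_like":
        pg = np.maximum(p, KL_EPSILON)
        qg = np.maximum(q, KL_EPSILON)
        return float(np.sum(qg * (np.log(qg) - np.log(pg))))
    raise ValueError(f"unknown metric {metric!r}; choose one of {METRICS}")


@dataclass(frozen=True)
class SolveResult:
    """Algebraic solution of the inverse race (may leave the simplex)."""

    p: np.ndarray
    feasible: bool
    violations: tuple[int, ...]
    pivot_failure: int | None = None


def solve_goal_distribution(
    q: np.ndarray | BinnedDist,
    Q: np.ndarray | BinnedDist,
    tol: float = 1e-9,
) -> SolveResult:
    """Solve the race equation for p given q and Q (both on N shared bins).

    The system is lower-triangular: equation i reduces to
    p_i (1 - Σ_{j<=i} q_j) = Q_i - q_i (1 - Σ_{j<i} p_j), solved in ascending
    i; the final component comes from normalization (the last equation is
    implied by the others when all three vectors are on the simplex).  The
    solution is returned even when infeasible, with the violating components
    flagged, so callers can fall back to constrained optimization.
    """
    qa = q.probs if isinstance(q, BinnedDist) else np.asarray(q, dtype=float)
    Qa = Q.probs if isinstance(Q, BinnedDist) else np.asarray(Q, dtype=float)
    if qa.size != Qa.size:
        raise ValueError("q and Q must share the same bins")
    n = qa.size
    cq = np.cumsum(qa)
    p = np.zeros(n)
    cum_p = 0.0
    for i in range(n - 1):
        denom = 1.0 - cq[i]
        numer = Qa[i] - qa[i] * (1.0 - cum_p)
        if abs(denom) < 1e-12:
            if abs(numer) < 1e-9:
                p[i] = 0.0
            else:
                return SolveResult(p, False, tuple(range(i, n)), pivot_failure=i)
        else:
            p[i] = numer / denom
        cum_p += p[i]
    p[n - 1] = 1.0 - cum_p
    violations = tuple(int(i) for i in np.flatnonzero(p < -tol))
    return SolveResult(p, feasible=len(violations) == 0, violations=violations)


@dataclass(frozen=True)
class PredictionResult:
    """Predicted goal distribution plus how it was obtained."""

    predicted: BinnedDist
    feasible_direct: bool
    objective_metric: str | None
    residual: float


def predict_goal_direct(
    equality: RaceEquality,
    samples: dict[str, np.ndarray],
    coarse_edges: np.ndarray,
) -> PredictionResult:
    """Prediction for the simple equalities: the binned side-2 race winner."""
    if equality.is_complex:
        raise ValueError(f"{equality.label} needs predict_goal_constrained")
    predicted = winner_distribution([samples[t] for t in equality.side2], coarse_edges)
    return PredictionResult(predicted, True, None, 0.0)


def _minimize_on_simplex(
    objective, n: int, starts: list[np.ndarray], tol: float = 1e-10
) -> tuple[np.ndarray, float]:
    """Multi-start SLSQP over the probability simplex."""
    cons = [{"type": "eq", "fun": lambda x: x.sum() - 1.0}]
    bounds = [(0.0, 1.0)] * n
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"ftol": tol, "maxiter": 300},
        )
        if res.fun < best_f and np.all(res.x > -1e-9):
            best_x, best_f = res.x, float(res.fun)
    if best_x is None:
        raise RuntimeError("constrained prediction failed to converge from any start")
    best_x = np.clip(best_x, 0.0, None)
    return best_x / best_x.sum(), best_f


def predict_goal_constrained(
    equality: RaceEquality,
    samples: dict[str, np.ndarray],
    coarse_edges: np.ndarray,
    objective_metric: str = "kl_like",
    rng: np.random.Generator | None = None,
) -> PredictionResult:
    """Prediction for the complex equalities (goal races on its own side).

    Tries the triangular solve first; if the algebraic solution violates the
    probability constraints, minimizes distance(race(p, q), Q) over the
    simplex with multi-start SLSQP (clipped algebraic solution plus random
    Dirichlet starts).
    """
    if not equality.is_complex:
        raise ValueError(f"{equality.label} has a direct prediction; use predict_goal_direct")
    q = winner_distribution([samples[t] for t in equality.part_types], coarse_edges)
    Q = winner_distribution([samples[t] for t in equality.side2], coarse_edges)
    sol = solve_goal_distribution(q, Q)
    if sol.feasible:
        p = np.clip(sol.p, 0.0, None)
        return PredictionResult(
            BinnedDist(probs=p / p.sum()), True, objective_metric, 0.0
        )

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, 0.0, None)
        s = x.sum()
        if s <= 0:
            return np.inf
        raced = forward_race(x / s, q)
        return distance(raced, Q, objective_metric)

    rng = rng or np.random.default_rng(0)
    n = q.probs.size
    clipped = np.clip(sol.p, 0.0, None)
    clipped = clipped / clipped.sum() if clipped.sum() > 0 else np.full(n, 1.0 / n)
    starts = [clipped, np.full(n, 1.0 / n)] + [rng.dirichlet(np.ones(n)) for _ in range(5)]
    p, resid = _minimize_on_simplex(objective, n, starts)
    return PredictionResult(BinnedDist(probs=p), False, objective_metric, resid)


def predict_goal(
    equality: RaceEquality,
    samples: dict[str, np.ndarray],
    coarse_edges: np.ndarray,
    objective_metric: str = "kl_like",
    rng: np.random.Generator | None = None,
) -> PredictionResult:
    """Dispatch to the direct or constrained prediction path."""
    if equality.is_complex:
        return predict_goal_constrained(equality, samples, coarse_edges, objective_metric, rng)
    return predict_goal_direct(equality, samples, coarse_edges)
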