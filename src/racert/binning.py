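"""Two-stage time binning for reaction-time distributions.

Reaction times of all singleton types entering a race equality are first
pooled and divided into ``L`` fine bins with (as close as possible) equal
sample counts.  A much coarser set of ``N`` bins is then drawn from the fine
boundaries: the outermost coarse edges bracket the pooled data range, two
optional edges hug the range of the goal-type samples, and the remaining
interior edges are placed at fine boundaries closest to chosen quantiles of
the goal-type samples (uniform or erf-spaced fractions).

Because every coarse edge is itself a fine edge, any distribution defined on
the fine bins can be aggregated to the coarse bins without splitting mass,
which is what lets the null construction commute with coarsening.

All bins are half-open ``[t_{i-1}, t_i)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "BinnedDist",
    "BinScheme",
    "F_SCHEMES",
    "fraction_targets",
    "fine_boundaries",
    "coarse_boundaries",
    "discretize",
    "aggregate_to_coarse",
]

#: allowed interior-fraction schemes: uniform spacing or erf spacing with one
#: of three steepness parameters.
F_SCHEMES = ("uniform", "erf:1.25", "erf:1.35", "erf:1.45")


@dataclass(frozen=True)
class BinnedDist:
    """A probability vector over coarse (or fine) time bins.

    ``probs`` always sums to 1; ``counts`` is present when the distribution
    was built from integer sample counts.
    """

    probs: np.ndarray
    counts: np.ndarray | None = None
    scheme_ref: str | None = None

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if np.any(p < -1e-12):
            raise ValueError("probs must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probs must sum to 1, got {p.sum()!r}")
        if self.counts is not None:
            c = np.asarray(self.counts)
            object.__setattr__(self, "counts", c)
            if c.shape != p.shape:
                raise ValueError("counts and probs must have the same length")

    @property
    def n_bins(self) -> int:
        return self.probs.size


@dataclass(frozen=True)
class BinScheme:
    """Fine and coarse bin boundaries for one (observer, equality) analysis."""

    fine_edges: np.ndarray
    coarse_edges: np.ndarray
    f_scheme: str = "erf:1.35"

    def __post_init__(self):
        fe = np.asarray(self.fine_edges, dtype=float)
        ce = np.asarray(self.coarse_edges, dtype=float)
        object.__setattr__(self, "fine_edges", fe)
        object.__setattr__(self, "coarse_edges", ce)
        if np.any(np.diff(fe) <= 0) or np.any(np.diff(ce) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        # every coarse edge must be a fine edge
        idx = np.searchsorted(fe, ce)
        if np.any(idx >= fe.size) or not np.allclose(fe[np.minimum(idx, fe.size - 1)], ce):
            raise ValueError("coarse edges must be a subset of fine edges")

    @property
    def L(self) -> int:
        return self.fine_edges.size - 1

    @property
    def N(self) -> int:
        return self.coarse_edges.size - 1

    def to_dict(self) -> dict:
        return {
            "fine_edges": self.fine_edges.tolist(),
            "coarse_edges": self.coarse_edges.tolist(),
            "f_scheme": self.f_scheme,
        }


def fraction_targets(f_scheme: str, n_interior: int) -> np.ndarray:
    """Quantile fractions F_1 < ... < F_{n'} for the interior coarse edges.

    ``uniform`` gives F_i = i/(n'+1); ``erf:x`` gives
    F_i = (erf(-x + 2x (i-1)/(n'-1)) + 1)/2, which crowds the edges toward
    the middle of the goal-sample distribution.
    """
    if n_interior < 1:
        return np.empty(0)
    if f_scheme == "uniform":
        i = np.arange(1, n_interior + 1, dtype=float)
        return i / (n_interior + 1)
    if f_scheme.startswith("erf:"):
        x = float(f_scheme.split(":", 1)[1])
        if n_interior == 1:
            return np.array([0.5])
        i = np.arange(n_interior, dtype=float)
        return 0.5 * (erf(-x + 2.0 * x * i / (n_interior - 1)) + 1.0)
    raise ValueError(f"unknown F scheme {f_scheme!r}; choose one of {F_SCHEMES}")


def fine_boundaries(pooled_samples: Sequence[float], L: int = 100) -> np.ndarray:
    """Equal-count fine boundaries T_0 < ... < T_L over pooled samples.

    Interior edges sit at midpoints between consecutive order statistics at
    the ranks that split the pool into L near-equal parts; the outermost
    edges bracket the data strictly (so the smallest/largest samples fall in
    the first/last half-open bin).  Duplicate candidate edges caused by tied
    samples are collapsed, reducing the effective L with a warning.
    """
    x = np.sort(np.asarray(pooled_samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pooled samples to build boundaries")
    if n < L + 1:
        warnings.warn(
            f"only {n} pooled samples; reducing L from {L} to {n - 1}", stacklevel=2
        )
        L = n - 1
    span = x[-1] - x[0]
    margin = 1e-9 + 1e-6 * max(span, 1.0)
    lo, hi = x[0] - margin, x[-1] + margin
    ranks = np.rint(np.arange(1, L) * n / L).astype(int)
    ranks = np.clip(ranks, 1, n - 1)
    interior = 0.5 * (x[ranks - 1] + x[ranks])
    edges = np.concatenate([[lo], interior, [hi]])
    edges = np.unique(edges)
    # midpoints of tied samples can coincide with data values; keep only
    # edges that leave the extreme samples strictly inside
    edges = edges[(edges >= lo) & (edges <= hi)]
    if edges.size < L + 1:
        warnings.warn(
            f"tied samples collapsed fine edges: effective L = {edges.size - 1} "
            f"instead of {L}",
            stacklevel=2,
        )
    if edges.size < 3:
        raise ValueError("too few distinct samples for any fine binning")
    return edges


def coarse_boundaries(
    fine_edges: np.ndarray,
    goal_samples: Sequence[float],
    pool_min: float,
    pool_max: float,
    N: int,
    f_scheme: str = "erf:1.35",
) -> np.ndarray:
    """Select N+1 coarse edges t_0 < ... < t_N from the fine edges.

    ``pool_min``/``pool_max`` are the extremes of the collective pool of
    goal samples, race-winner samples of the predicting side and (for the
    complex equalities) the partial-race winner samples.  t_0 is the largest
    fine edge below ``pool_min`` and t_N the smallest above ``pool_max``.
    If the goal samples span a strictly smaller range, t_1 (t_{N-1}) is the
    largest (smallest) fine edge below (above) the goal minimum (maximum).
    Remaining interior edges go to the unassigned fine edges closest to the
    goal-sample quantiles at the scheme fractions; exact ties pick the
    smaller edge.
    """
    T = np.asarray(fine_edges, dtype=float)
    goal = np.asarray(goal_samples, dtype=float)
    if goal.size == 0:
        raise ValueError("goal_samples must be non-empty")
    if N < 2:
        raise ValueError("need N >= 2 coarse bins")

    below = T[T < pool_min]
    above = T[T > pool_max]
    if below.size == 0 or above.size == 0:
        raise ValueError("fine edges do not bracket the pooled sample range")
    t0, tN = below.max(), above.min()

    t1 = tNm1 = None
    gmin, gmax = goal.min(), goal.max()
    if gmin > pool_min:
        cand = T[T < gmin]
        if cand.size and cand.max() > t0:
            t1 = cand.max()
    if gmax < pool_max:
        cand = T[T > gmax]
        if cand.size and cand.min() < tN:
            tNm1 = cand.min()

    n_special = (t1 is not None) + (tNm1 is not None)
    n_interior = N - 1 - n_special
    if n_interior < 0:
        raise ValueError(f"N={N} too small for the special edge rules")

    fractions = fraction_targets(f_scheme, n_interior)
    targets = np.quantile(goal, fractions) if n_interior else np.empty(0)

    lo = t1 if t1 is not None else t0
    hi = tNm1 if tNm1 is not None else tN
    pool = sorted(T[(T > lo) & (T < hi)])
    chosen: list[float] = []
    for tau in targets:
        if not pool:
            raise ValueError(
                f"cannot place {n_interior} interior coarse edges; use a smaller N"
            )
        dist = [abs(e - tau) for e in pool]
        k = int(np.argmin(dist))  # argmin returns the first (smaller) on ties
        chosen.append(pool.pop(k))

    edges = [t0] + ([t1] if t1 is not None else []) + sorted(chosen) + (
        [tNm1] if tNm1 is not None else []
    ) + [tN]
    edges = np.asarray(edges, dtype=float)
    if edges.size != N + 1 or np.any(np.diff(edges) <= 0):
        raise ValueError(
            f"could not build {N + 1} strictly increasing coarse edges "
            f"(got {edges.size}); use a smaller N"
        )
    return edges


def discretize(samples: Sequence[float], edges: np.ndarray) -> BinnedDist:
    """Histogram samples into half-open bins [t_{i-1}, t_i) and normalize."""
    x = np.asarray(samples, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if x.size == 0:
        raise ValueError("cannot form a distribution from zero samples")
    idx = np.searchsorted(edges, x, side="right") - 1
    bad = (idx < 0) | (idx >= edges.size - 1)
    if np.any(bad):
        raise ValueError(
            f"sample(s) outside binning range [{edges[0]}, {edges[-1]}): "
            f"{x[bad][:5].tolist()}"
        )
    counts = np.bincount(idx, minlength=edges.size - 1)
    return BinnedDist(probs=counts / counts.sum(), counts=counts)


def aggregate_to_coarse(
    fine_probs: np.ndarray, fine_edges: np.ndarray, coarse_edges: np.ndarray
) -> np.ndarray:
    """Sum fine-bin masses into coarse bins (coarse edges ⊂ fine edges).

    Fine bins outside [t_0, t_N) are dropped, and the result is renormalized;
    for distributions supported inside the coarse range this is a pure
    aggregation.
    """
    fine_probs = np.asarray(fine_probs, dtype=float)
    pos = np.searchsorted(fine_edges, coarse_edges)
    if not np.allclose(fine_edges[np.clip(pos, 0, fine_edges.size - 1)], coarse_edges):
        raise ValueError("coarse edges are not a subset of fine edges")
    out = np.array(
        [fine_probs[pos[i] : pos[i + 1]].sum() for i in range(pos.size - 1)]
    )
    total = out.sum()
    if total <= 0:
        raise ValueError("no fine-bin mass inside the coarse range")
    return out / total
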