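"""Race equalities between reaction-time distributions and their algebra.

A race equality states that one reaction-time law equals the law of the
minimum of independent draws from other conditions ("statistical
facilitation": the winner of a race among independent racers).  Eight
equalities over the seven singleton types (C, M, O and their conjunctions)
are analyzed; only the first — min(RT_CMO, RT_C, RT_M, RT_O) =P
min(RT_CM, RT_CO, RT_MO) — rests on neural assumptions believed true of V1
(no triple-conjunction cells), so it alone is flagged non-spurious.

The module provides the catalog of equalities, exhaustive race-winner
enumeration, and an equivalent survival-product shortcut for the binned
winner distribution (the production path: enumeration is O(Π n_k)).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import reduce
from typing import Sequence

import numpy as np

from .binning import BinnedDist

__all__ = [
    "SingletonType",
    "SINGLETON_TYPES",
    "RaceEquality",
    "WinnerSamples",
    "equality_catalog",
    "winner_samples",
    "winner_minmax",
    "winner_distribution",
    "forward_race",
    "race_of_binned",
]


class SingletonType(str, Enum):
    """Feature singleton categories: unique in color, motion, orientation
    or any combination thereof."""

    C = "C"
    M = "M"
    O = "O"
    CM = "CM"
    CO = "CO"
    MO = "MO"
    CMO = "CMO"


SINGLETON_TYPES: tuple[str, ...] = tuple(t.value for t in SingletonType)


@dataclass(frozen=True)
class RaceEquality:
    """A declared equality RT1 =P RT2 with a designated goal type.

    ``side1`` and ``side2`` list the racer singleton types of each side; the
    goal type (the most feature-rich singleton in the equality) is the one
    whose distribution is predicted from the others.
    """

    label: str
    side1: tuple[str, ...]
    side2: tuple[str, ...]
    goal: str
    spurious: bool

    def __post_init__(self):
        in1, in2 = self.goal in self.side1, self.goal in self.side2
        if in1 == in2:
            raise ValueError("goal must appear in exactly one side")

    @property
    def is_complex(self) -> bool:
        """True when the goal races against other types on its own side
        (RE1, RE6-RE8), requiring the inverse race solve."""
        return len(self.side1) > 1

    @property
    def part_types(self) -> tuple[str, ...]:
        """Racers sharing the goal's side (the partial race RT_part)."""
        return tuple(t for t in self.side1 if t != self.goal)

    @property
    def all_types(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.side1 + self.side2:
            if t not in seen:
                seen.append(t)
        return tuple(seen)


@dataclass(frozen=True)
class WinnerSamples:
    """Race-winner samples: the minimum over one sample from each racer,
    for every cross-combination of the racers' samples."""

    values: np.ndarray
    source_counts: tuple[int, ...]


def equality_catalog() -> dict[str, RaceEquality]:
    """The eight race equalities under study, keyed RE1..RE8."""
    cat = [
        RaceEquality("RE1", ("CMO", "C", "M", "O"), ("CM", "CO", "MO"), "CMO", False),
        RaceEquality("RE2", ("CO",), ("C", "O"), "CO", True),
        RaceEquality("RE3", ("MO",), ("M", "O"), "MO", True),
        RaceEquality("RE4", ("CM",), ("C", "M"), "CM", True),
        RaceEquality("RE5", ("CMO",), ("C", "M", "O"), "CMO", True),
        RaceEquality("RE6", ("CMO", "M", "CO"), ("C", "O", "CM", "MO"), "CMO", True),
        RaceEquality("RE7", ("CMO", "C", "MO"), ("M", "O", "CM", "CO"), "CMO", True),
        RaceEquality("RE8", ("CMO", "O", "CM"), ("C", "M", "CO", "MO"), "CMO", True),
    ]
    return {eq.label: eq for eq in cat}


def winner_samples(racer_samples: Sequence[Sequence[float]]) -> WinnerSamples:
    """Enumerate all cross-combinations of racer samples and return the
    per-combination minimum (exhaustive; use only for small inputs)."""
    if len(racer_samples) == 0:
        raise ValueError("need at least one racer")
    arrays = [np.asarray(a, dtype=float) for a in racer_samples]
    for k, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"racer {k} has no samples")
    k = len(arrays)
    shaped = [
        a.reshape([-1 if i == j else 1 for i in range(k)]) for j, a in enumerate(arrays)
    ]
    mins = reduce(np.minimum, shaped).ravel()
    return WinnerSamples(values=mins, source_counts=tuple(a.size for a in arrays))


def winner_minmax(racer_samples: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Min and max of the enumerated winner samples, without enumeration.

    The smallest winner is the overall smallest sample; the largest winner is
    the smallest of the racers' maxima (the combination of all maxima).
    """
    arrays = [np.asarray(a, dtype=float) for a in racer_samples]
    return min(a.min() for a in arrays), min(a.max() for a in arrays)


def _empirical_survival(samples: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """P(X >= t) at each edge, as an exact count fraction."""
    s = np.sort(samples)
    below = np.searchsorted(s, edges, side="left")  # #{x < t}
    return (s.size - below) / s.size


def winner_distribution(
    racer_samples: Sequence[Sequence[float]], edges: np.ndarray
) -> BinnedDist:
    """Binned distribution of the race winner via survival products.

    For half-open bins, the fraction of winner combinations at or beyond an
    edge t factorizes as Π_k #{x_k >= t}/n_k, so the bin masses are exact
    differences of survival products — identical to binning the enumerated
    winner samples, at O(Σ n_k log n_k) cost.
    """
    if len(racer_samples) == 0:
        raise ValueError("need at least one racer")
    edges = np.asarray(edges, dtype=float)
    arrays = [np.asarray(a, dtype=float) for a in racer_samples]
    for k, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"racer {k} has no samples")
    wmin, wmax = winner_minmax(arrays)
    if wmin < edges[0] or wmax >= edges[-1]:
        raise ValueError(
            f"winner samples [{wmin}, {wmax}] fall outside the binning "
            f"range [{edges[0]}, {edges[-1]})"
        )
    surv = np.prod([_empirical_survival(a, edges) for a in arrays], axis=0)
    probs = surv[:-1] - surv[1:]
    probs = np.clip(probs, 0.0, None)
    return BinnedDist(probs=probs / probs.sum())


def forward_race(p: BinnedDist | np.ndarray, q: BinnedDist | np.ndarray) -> BinnedDist:
    """Distribution of the race winner between two independent binned RTs.

    P_i = p_i (1 - Σ_{j<=i} q_j) + q_i (1 - Σ_{j<=i} p_j) + p_i q_i:
    either p wins in bin i with q strictly later, or q wins with p strictly
    later, or both land in bin i.  Commutative and associative.
    """
    pa = p.probs if isinstance(p, BinnedDist) else np.asarray(p, dtype=float)
    qa = q.probs if isinstance(q, BinnedDist) else np.asarray(q, dtype=float)
    if pa.size != qa.size:
        raise ValueError("p and q must be binned over the same bins")
    cp, cq = np.cumsum(pa), np.cumsum(qa)
    out = pa * (1.0 - cq) + qa * (1.0 - cp) + pa * qa
    out = np.clip(out, 0.0, None)
    return BinnedDist(probs=out / out.sum())


def race_of_binned(dists: Sequence[BinnedDist | np.ndarray]) -> np.ndarray:
    """Race-winner distribution of any number of independent binned RTs,
    via survival products over the shared bin edges."""
    if len(dists) == 0:
        raise ValueError("need at least one distribution")
    mats = [
        d.probs if isinstance(d, BinnedDist) else np.asarray(d, dtype=float)
        for d in dists
    ]
    n = mats[0].size
    if any(m.size != n for m in mats):
        raise ValueError("all distributions must share the same bins")
    surv = np.ones(n + 1)
    for m in mats:
        s = np.concatenate([[1.0], 1.0 - np.cumsum(m)])
        surv = surv * np.clip(s, 0.0, None)
    probs = np.clip(surv[:-1] - surv[1:], 0.0, None)
    return probs / probs.sum()
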