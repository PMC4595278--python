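"""A toy-V1 observer that generates singleton-search reaction times.

Each singleton type evokes, on every trial, one independent response from
each neuron type tuned to at least one of the singleton's unique feature
dimensions (its "non-trivial" responses; responses of other neuron types are
statistically identical to background responses and never determine the
maximum).  Reaction time is a monotonically decreasing function of the
maximum non-trivial response — so the RT to a compound singleton is the race
winner of the RTs its component responses would produce alone.

The response family (lognormal) and the decreasing mapping (reciprocal or
exponential) are stand-ins: the race-equality structure of the generated
data is provably independent of both, and the test suite checks that claim
by running the theorem-level tests under two different mappings.

Iso-feature suppression enters through the response magnitudes: a
conjunction cell responds far more vigorously when the singleton is unique
in all of its tuned dimensions (fully released from suppression) than when
only one dimension is unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Sequence

import numpy as np
import pandas as pd

from .rt_io import RTDataset

__all__ = [
    "FEATURE_DIMS",
    "ResponseSpec",
    "ResponseModel",
    "RTMapping",
    "SceneSpec",
    "scenario_preset",
    "calibrate_gain",
    "default_mapping",
    "sample_rts",
    "sample_trial",
    "sample_race_rts",
    "generate_dataset",
    "inject_contamination",
    "generate_scene",
]

#: feature dimensions each singleton/neuron label is tuned to / unique in
FEATURE_DIMS: dict[str, frozenset] = {
    "C": frozenset({"color"}),
    "M": frozenset({"motion"}),
    "O": frozenset({"orientation"}),
    "CM": frozenset({"color", "motion"}),
    "CO": frozenset({"color", "orientation"}),
    "MO": frozenset({"motion", "orientation"}),
    "CMO": frozenset({"color", "motion", "orientation"}),
}


@dataclass(frozen=True)
class ResponseSpec:
    """Lognormal firing-rate distribution (median in spikes/s, log-scale SD)."""

    median: float
    sigma: float = 0.3

    def sample(
        self, rng: np.random.Generator, size=None, scale: float = 1.0
    ) -> np.ndarray:
        return rng.lognormal(log(self.median * scale), self.sigma, size)


@dataclass(frozen=True)
class ResponseModel:
    """Response distributions of every neuron type present in the cortex.

    ``neurons[X][s]`` is the response of neuron type X to a singleton whose
    unique dimensions intersect X's tuned dimensions in exactly the set
    ``s`` (larger ``s`` = more release from iso-feature suppression).
    ``background[X]`` is X's response to a background bar (doubly
    suppressed; never the trial maximum by the saliency assumption).
    """

    name: str
    neurons: dict[str, dict[frozenset, ResponseSpec]]
    background: dict[str, ResponseSpec]

    def nontrivial_specs(self, singleton: str) -> list[ResponseSpec]:
        sdims = FEATURE_DIMS[singleton]
        specs = []
        for x, table in self.neurons.items():
            overlap = frozenset(FEATURE_DIMS[x] & sdims)
            if overlap:
                specs.append(table[overlap])
        if not specs:
            raise ValueError(f"model {self.name!r} has no neuron responding to {singleton}")
        return specs


@dataclass(frozen=True)
class RTMapping:
    """Monotone decreasing response-to-RT mapping with a floor.

    ``reciprocal``: RT = floor + gain / r (gain in s·spikes/s);
    ``exponential``: RT = floor + gain · exp(-r / exp_scale) (gain in s).
    """

    gain: float
    floor: float = 0.3
    form: str = "reciprocal"
    exp_scale: float = 20.0

    def decreasing_part(self, r: np.ndarray) -> np.ndarray:
        """The monotone decreasing factor g(r) with RT = floor + gain·g(r)."""
        r = np.asarray(r, dtype=float)
        if self.form == "reciprocal":
            return 1.0 / r
        if self.form == "exponential":
            return np.exp(-r / self.exp_scale)
        raise ValueError(f"unknown mapping form {self.form!r}")

    def rt(self, r: np.ndarray, gain_scale: float = 1.0) -> np.ndarray:
        return self.floor + self.gain * gain_scale * self.decreasing_part(r)


def _conjunction_table(partial: ResponseSpec, full: ResponseSpec, dims: frozenset):
    table = {frozenset({d}): partial for d in dims}
    if len(dims) == 3:
        # triple-conjunction cell: pairwise release sits between the two
        for a in dims:
            table[frozenset(dims - {a})] = ResponseSpec(
                median=np.sqrt(partial.median * full.median), sigma=partial.sigma
            )
    table[dims] = full
    return table


def scenario_preset(name: str) -> ResponseModel:
    """Named cortical scenarios.

    ``no_conjunction``: only C, M, O cells — every race equality holds by
    construction.  ``v1_like``: adds CO and MO conjunction cells (CM cells
    are reported scarce, CMO cells absent), whose fully-released responses
    dominate — the double/triple-feature equalities RE2, RE3, RE5 (and their
    corollaries RE6, RE7) break, while RE1, RE4, RE8 hold.  ``cmo_present``:
    adds a triple-conjunction cell, which breaks even RE1.
    """
    single = ResponseSpec(median=20.0, sigma=0.3)
    bg = ResponseSpec(median=6.0, sigma=0.3)
    singles = {
        x: {FEATURE_DIMS[x]: single} for x in ("C", "M", "O")
    }
    background = {x: bg for x in ("C", "M", "O")}
    if name == "no_conjunction":
        return ResponseModel("no_conjunction", singles, background)

    partial = ResponseSpec(median=12.0, sigma=0.3)
    full = ResponseSpec(median=30.0, sigma=0.3)
    conj = {
        x: _conjunction_table(partial, full, FEATURE_DIMS[x]) for x in ("CO", "MO")
    }
    background = {**background, "CO": bg, "MO": bg}
    if name == "v1_like":
        return ResponseModel("v1_like", {**singles, **conj}, background)
    if name == "cmo_present":
        cmo = _conjunction_table(
            ResponseSpec(median=12.0, sigma=0.3),
            ResponseSpec(median=45.0, sigma=0.3),
            FEATURE_DIMS["CMO"],
        )
        return ResponseModel(
            "cmo_present",
            {**singles, **conj, "CMO": cmo},
            {**background, "CMO": bg},
        )
    raise ValueError(
        f"unknown preset {name!r}; choose no_conjunction, v1_like or cmo_present"
    )


_GAIN_CACHE: dict[tuple[str, str, float, float], float] = {}


def calibrate_gain(
    model: ResponseModel,
    form: str = "reciprocal",
    floor: float = 0.3,
    target_mean: float = 0.6,
    n: int = 200_000,
    seed: int = 20150904,
) -> float:
    """Gain making the mean single-feature RT equal ``target_mean``.

    Solves gain = (target - floor) / E[g(max response)] with the expectation
    over the three single-feature singletons, estimated once by a large
    fixed-seed Monte-Carlo draw and cached per named preset.
    """
    key = (model.name, form, floor, target_mean)
    if model.name != "custom" and key in _GAIN_CACHE:
        return _GAIN_CACHE[key]
    rng = np.random.default_rng(seed)
    mapping = RTMapping(gain=1.0, floor=floor, form=form)
    means = []
    for singleton in ("C", "M", "O"):
        specs = model.nontrivial_specs(singleton)
        rmax = np.max([s.sample(rng, n) for s in specs], axis=0)
        means.append(np.mean(mapping.decreasing_part(rmax)))
    gain = (target_mean - floor) / float(np.mean(means))
    _GAIN_CACHE[key] = gain
    return gain


def default_mapping(model: ResponseModel, form: str = "reciprocal") -> RTMapping:
    """Calibrated mapping for a preset (0.3 s floor, 0.6 s single-feature mean)."""
    return RTMapping(gain=calibrate_gain(model, form=form), form=form)


def sample_rts(
    model: ResponseModel,
    mapping: RTMapping,
    singleton: str,
    n: int,
    rng: np.random.Generator,
    gain_scale: float = 1.0,
    response_scale: float = 1.0,
) -> np.ndarray:
    """n independent reaction times for one singleton type.

    Draws every non-trivial response independently, takes the maximum and
    applies the mapping.  Background responses are drawn for diagnostics but
    clipped below the singleton response — the generator enforces the
    assumption that the singleton is always the most salient item.
    """
    specs = model.nontrivial_specs(singleton)
    draws = np.stack([s.sample(rng, n, scale=response_scale) for s in specs])
    rmax = draws.max(axis=0)
    if model.background:
        bg = np.stack(
            [s.sample(rng, n, scale=response_scale) for s in model.background.values()]
        ).max(axis=0)
        bg = np.minimum(bg, 0.999 * rmax)  # saliency holds by construction
        assert np.all(bg < rmax)
    return mapping.rt(rmax, gain_scale=gain_scale)


def sample_trial(
    model: ResponseModel,
    mapping: RTMapping,
    singleton: str,
    rng: np.random.Generator,
    gain_scale: float = 1.0,
    response_scale: float = 1.0,
) -> float:
    """Reaction time of a single trial."""
    return float(
        sample_rts(model, mapping, singleton, 1, rng, gain_scale, response_scale)[0]
    )


def sample_race_rts(
    model: ResponseModel,
    mapping: RTMapping,
    racer_types: Sequence[str],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n independent race-winner RTs: one fresh RT per racer type, minimized.

    Used for theorem-level checks, where both sides of an equality must be
    sampled as genuinely independent race outcomes.
    """
    rts = np.stack(
        [sample_rts(model, mapping, t, n, rng) for t in racer_types]
    )
    return rts.min(axis=0)


def generate_dataset(
    model: ResponseModel,
    mapping: RTMapping | None = None,
    n_per_type: int = 300,
    observers: int | Sequence[str] = 1,
    seed: int = 0,
    singletons: Sequence[str] = tuple(FEATURE_DIMS),
    gain_jitter_sd: float = 0.05,
    response_jitter_sd: float = 0.05,
) -> RTDataset:
    """Per-trial RT dataset: ``n_per_type`` trials per observer and singleton
    type, split as evenly as possible between randomly interleaved purple and
    green scenes (the model is color-symmetric).

    Observer individuality enters as multiplicative lognormal jitter on the
    mapping gain and on all response magnitudes.  All trials are generated
    correct; contamination is a separate step (``inject_contamination``).
    Fully reproducible from ``seed``.
    """
    if mapping is None:
        mapping = default_mapping(model)
    if isinstance(observers, int):
        observers = tuple(f"S{i + 1:02d}" for i in range(observers))
    ss = np.random.SeedSequence(seed)
    rows = []
    for obs_id, child in zip(observers, ss.spawn(len(observers))):
        rng = np.random.default_rng(child)
        gain_scale = float(rng.lognormal(0.0, gain_jitter_sd))
        response_scale = float(rng.lognormal(0.0, response_jitter_sd))
        for singleton in singletons:
            rts = sample_rts(
                model, mapping, singleton, n_per_type, rng, gain_scale, response_scale
            )
            colors = np.array(
                ["purple"] * ((n_per_type + 1) // 2) + ["green"] * (n_per_type // 2)
            )
            colors = colors[rng.permutation(n_per_type)]
            for rt, color in zip(rts, colors):
                rows.append((obs_id, singleton, color, float(rt), True))
    df = pd.DataFrame(rows, columns=[
        "observer_id", "singleton", "scene_color", "rt_seconds", "correct",
    ])
    return RTDataset(df, provenance=f"synthetic:{model.name} seed={seed}")


def inject_contamination(
    data: RTDataset,
    fast_guess_rate: float = 0.0,
    error_rate: float = 0.0,
    slow_outlier_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RTDataset:
    """Append fast guesses (< 0.2 s), error trials and far-tail slow trials
    at the given per-group rates, to exercise the exclusion pipeline."""
    for r in (fast_guess_rate, error_rate, slow_outlier_rate):
        if not 0.0 <= r < 1.0:
            raise ValueError("contamination rates must lie in [0, 1)")
    if fast_guess_rate == error_rate == slow_outlier_rate == 0.0:
        return data
    rng = rng or np.random.default_rng()
    rows = []
    for (obs, sing), grp in data.df.groupby(["observer_id", "singleton"]):
        rts = grp["rt_seconds"].to_numpy()
        n = len(grp)
        mean, sd = rts.mean(), rts.std(ddof=1) if n > 1 else 0.1

        def _color():
            return rng.choice(grp["scene_color"].to_numpy())

        for _ in range(round(fast_guess_rate * n)):
            rows.append((obs, sing, _color(), float(rng.uniform(0.05, 0.19)), True))
        for _ in range(round(error_rate * n)):
            rows.append((obs, sing, _color(), float(rng.choice(rts)), False))
        for _ in range(round(slow_outlier_rate * n)):
            rows.append(
                (obs, sing, _color(), float(mean + rng.uniform(4.0, 8.0) * sd), True)
            )
    extra = pd.DataFrame(rows, columns=list(data.df.columns))
    df = pd.concat([data.df, extra], ignore_index=True)
    return RTDataset(df, provenance=data.provenance + " [contaminated]")


@dataclass(frozen=True)
class SceneSpec:
    """Stimulus geometry of one search display."""

    rows: int = 30
    cols: int = 22
    extent_deg: tuple[float, float] = (39.0, 29.0)
    bar_deg: tuple[float, float] = (1.0, 0.2)
    eccentricity_deg: float = 12.8
    n_candidate_positions: int = 18
    jitter: bool = True
    scene_color: str = "purple"

    @property
    def n_items(self) -> int:
        return self.rows * self.cols


def _candidate_positions(spec: SceneSpec, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Indices of the grid cells nearest the target eccentricity, half on
    each side of the vertical midline."""
    d = np.abs(np.hypot(xs, ys) - spec.eccentricity_deg)
    half = spec.n_candidate_positions // 2
    left = np.flatnonzero(xs < 0)
    right = np.flatnonzero(xs > 0)
    pick_left = left[np.argsort(d[left])[:half]]
    pick_right = right[np.argsort(d[right])[:half]]
    return np.concatenate([pick_left, pick_right])


def generate_scene(
    spec: SceneSpec, singleton: str, rng: np.random.Generator
) -> dict:
    """Scene metadata: a jittered grid of identical background bars plus one
    singleton, unique in exactly the dimensions named by its type, near one
    of the candidate eccentric locations."""
    w, h = spec.extent_deg
    dx, dy = w / spec.cols, h / spec.rows
    cx = (np.arange(spec.cols) + 0.5) * dx - w / 2
    cy = (np.arange(spec.rows) + 0.5) * dy - h / 2
    xs, ys = (a.ravel() for a in np.meshgrid(cx, cy))
    if spec.jitter:
        xs = xs + rng.uniform(-0.2 * dx, 0.2 * dx, xs.size)
        ys = ys + rng.uniform(-0.2 * dy, 0.2 * dy, ys.size)

    other_color = "green" if spec.scene_color == "purple" else "purple"
    bg = {
        "color": spec.scene_color,
        "orientation": rng.choice(["left", "right"]),
        "motion": rng.choice(["left", "right"]),
    }
    flip = {"left": "right", "right": "left"}
    items = pd.DataFrame({
        "x_deg": xs,
        "y_deg": ys,
        "color": bg["color"],
        "orientation": bg["orientation"],
        "motion": bg["motion"],
    })
    sing_idx = int(rng.choice(_candidate_positions(spec, xs, ys)))
    for dim in FEATURE_DIMS[singleton]:
        if dim == "color":
            items.loc[sing_idx, "color"] = other_color
        else:
            items.loc[sing_idx, dim] = flip[bg[dim]]
    return {"items": items, "singleton_index": sing_idx, "singleton": singleton,
            "spec": spec}
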