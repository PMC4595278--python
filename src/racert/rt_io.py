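"""Per-trial reaction-time tables: loading, canonical writing, trial
exclusion and scene-color splitting.

The CSV dialect is ``observer_id,singleton,scene_color,rt_seconds,correct``
with a header row, RTs in seconds and ``correct`` as 0/1.  Exclusions follow
the standard psychophysics pipeline: error trials, anticipations faster than
0.2 s, and RTs more than 3 SD above the per-(observer, singleton) mean are
dropped.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .race_algebra import SINGLETON_TYPES

__all__ = [
    "COLUMNS",
    "SCENE_COLORS",
    "RTDataset",
    "ExclusionReport",
    "load_rt_table",
    "write_rt_table",
    "apply_exclusions",
    "split_by_scene_color",
]

COLUMNS = ("observer_id", "singleton", "scene_color", "rt_seconds", "correct")
SCENE_COLORS = ("purple", "green")


@dataclass
class RTDataset:
    """Per-trial reaction times keyed by (observer, singleton, scene color)."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def observers(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["observer_id"].unique()))

    def samples(
        self,
        observer_id: str | None = None,
        singleton: str | None = None,
        scene_color: str | None = None,
    ) -> np.ndarray:
        """RT samples for one cell, in stored (trial) order."""
        m = pd.Series(True, index=self.df.index)
        if observer_id is not None:
            m &= self.df["observer_id"] == observer_id
        if singleton is not None:
            m &= self.df["singleton"] == singleton
        if scene_color is not None:
            m &= self.df["scene_color"] == scene_color
        return self.df.loc[m, "rt_seconds"].to_numpy(dtype=float)

    def sample_map(
        self, observer_id: str, types: tuple[str, ...], scene_color: str | None = None
    ) -> dict[str, np.ndarray]:
        """RT samples per singleton type for one observer (and scene pool)."""
        return {t: self.samples(observer_id, t, scene_color) for t in types}

    def subset(self, mask: pd.Series, provenance: str | None = None) -> "RTDataset":
        return RTDataset(
            self.df.loc[mask].reset_index(drop=True),
            provenance if provenance is not None else self.provenance,
        )


@dataclass
class ExclusionReport:
    """Counts of trials removed per exclusion reason."""

    incorrect: int = 0
    too_fast: int = 0
    too_slow: int = 0
    skipped_sd_groups: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.incorrect + self.too_fast + self.too_slow

    def to_dict(self) -> dict:
        return {
            "incorrect": self.incorrect,
            "too_fast": self.too_fast,
            "too_slow": self.too_slow,
            "total": self.total,
            "skipped_sd_groups": [list(g) for g in self.skipped_sd_groups],
        }


def _validate(df: pd.DataFrame, source: str) -> None:
    """Row-level validation; reports 1-based data-row numbers on failure."""
    rt = pd.to_numeric(df["rt_seconds"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(rt) | (rt <= 0))
    if bad.size:
        raise ValueError(
            f"{source}: unparseable or non-positive rt_seconds on data row "
            f"{bad[0] + 1}: {df['rt_seconds'].iloc[bad[0]]!r}"
        )
    bad = np.flatnonzero(~df["singleton"].isin(SINGLETON_TYPES))
    if bad.size:
        raise ValueError(
            f"{source}: unknown singleton type on data row {bad[0] + 1}: "
            f"{df['singleton'].iloc[bad[0]]!r}"
        )
    bad = np.flatnonzero(~df["scene_color"].isin(SCENE_COLORS))
    if bad.size:
        raise ValueError(
            f"{source}: unknown scene_color on data row {bad[0] + 1}: "
            f"{df['scene_color'].iloc[bad[0]]!r}"
        )
    bad = np.flatnonzero(~df["correct"].astype(str).isin(["0", "1", "True", "False"]))
    if bad.size:
        raise ValueError(
            f"{source}: correct flag must be 0/1 on data row {bad[0] + 1}: "
            f"{df['correct'].iloc[bad[0]]!r}"
        )


def load_rt_table(path: str | Path) -> RTDataset:
    """Read a per-trial RT table from CSV, validating every row."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s): {missing}")
    _validate(df, path.name)
    out = pd.DataFrame(
        {
            "observer_id": df["observer_id"].astype(str),
            "singleton": df["singleton"].astype(str),
            "scene_color": df["scene_color"].astype(str),
            # Python float() is correctly rounded, so load(write(x)) is exact
            "rt_seconds": df["rt_seconds"].map(float),
            "correct": df["correct"].map(
                {"0": False, "1": True, "False": False, "True": True}
            ),
        }
    )
    return RTDataset(out, provenance=str(path))


def write_rt_table(data: RTDataset, path: str | Path) -> None:
    """Write the canonical CSV form (header, correct as 0/1, shortest float
    repr for RTs, so write→load→write is byte-identical)."""
    df = data.df.copy()
    df["correct"] = df["correct"].astype(int)
    Path(path).write_text(df.to_csv(index=False, lineterminator="\n"))


def apply_exclusions(
    data: RTDataset,
    min_rt: float = 0.2,
    sd_multiplier: float = 3.0,
) -> tuple[RTDataset, ExclusionReport]:
    """Remove error trials, anticipations and slow outliers.

    Incorrect trials and RTs below ``min_rt`` are dropped first; the mean and
    SD used by the ``sd_multiplier``-SD upper cut are then computed once per
    (observer, singleton) group on the surviving trials (a single,
    non-iterated pass).  Groups left with fewer than two trials skip the SD
    cut with a warning.
    """
    df = data.df
    report = ExclusionReport()
    correct = df["correct"].astype(bool)
    fast = df["rt_seconds"] < min_rt
    report.incorrect = int((~correct).sum())
    report.too_fast = int((correct & fast).sum())
    keep = correct & ~fast

    drop_slow = pd.Series(False, index=df.index)
    for (obs, sing), idx in df.loc[keep].groupby(["observer_id", "singleton"]).groups.items():
        rts = df.loc[idx, "rt_seconds"]
        if len(rts) < 2:
            warnings.warn(
                f"group ({obs}, {sing}) has <2 surviving trials; SD filter skipped",
                stacklevel=2,
            )
            report.skipped_sd_groups.append((str(obs), str(sing)))
            continue
        cutoff = rts.mean() + sd_multiplier * rts.std(ddof=1)
        drop_slow.loc[idx] = rts > cutoff
    report.too_slow = int(drop_slow.sum())
    out = data.subset(keep & ~drop_slow, provenance=data.provenance + " [filtered]")
    return out, report


def split_by_scene_color(data: RTDataset) -> tuple[RTDataset, RTDataset]:
    """Partition trials into (purple, green) scene pools."""
    purple = data.df["scene_color"] == "purple"
    return (
        data.subset(purple, data.provenance + " [purple]"),
        data.subset(~purple, data.provenance + " [green]"),
    )
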