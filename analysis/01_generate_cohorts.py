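#!/usr/bin/env python
"""Generate the two synthetic observer cohorts the analysis runs on.

Cohort A ("v1like"): six observers from a cortex with CO and MO conjunction
cells (CM scarce, no triple-conjunction cells) — the double/triple-feature
race equalities should break, the non-spurious one should hold.
Cohort B ("control"): six observers from a cortex with only single-feature
cells — every race equality holds by construction.

Both cohorts get realistic trial contamination (fast guesses, button errors,
slow outliers) to exercise the exclusion pipeline.  300 trials per singleton
type and observer, split ~150/150 between purple and green scenes.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from racert.rt_io import write_rt_table
from racert.synthetic_observer import (
    generate_dataset,
    inject_contamination,
    scenario_preset,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20260921


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for tag, preset, seed in [("v1like", "v1_like", SEED),
                              ("control", "no_conjunction", SEED + 1)]:
        model = scenario_preset(preset)
        data = generate_dataset(model, n_per_type=300, observers=6, seed=seed)
        data = inject_contamination(
            data, fast_guess_rate=0.02, error_rate=0.05, slow_outlier_rate=0.01,
            rng=np.random.default_rng(seed + 7),
        )
        out = RESULTS / f"cohort_{tag}_raw.csv"
        write_rt_table(data, out)
        single = np.concatenate(
            [data.samples(singleton=t) for t in ("C", "M", "O")]
        )
        print(f"{tag}: {len(data)} trials -> {out.name}")
        print(f"  single-feature mean RT {single.mean():.3f} s "
              f"(calibration target 0.6 s before contamination)")


if __name__ == "__main__":
    main()
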