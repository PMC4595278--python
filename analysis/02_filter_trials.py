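#!/usr/bin/env python
"""Apply the standard trial exclusions to the raw cohorts.

Removes error trials, reaction times below 0.2 s, and reaction times more
than 3 SD above the per-(observer, singleton) mean, then writes the filtered
tables and a per-cohort exclusion report.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from racert.rt_io import apply_exclusions, load_rt_table, write_rt_table

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    reports = {}
    for tag in ("v1like", "control"):
        raw = load_rt_table(RESULTS / f"cohort_{tag}_raw.csv")
        filtered, report = apply_exclusions(raw)
        write_rt_table(filtered, RESULTS / f"cohort_{tag}_filtered.csv")
        reports[tag] = report.to_dict()
        kept = 100 * len(filtered) / len(raw)
        print(f"{tag}: kept {len(filtered)}/{len(raw)} trials ({kept:.1f}%)")
        print(f"  excluded — errors: {report.incorrect}, "
              f"fast (<0.2 s): {report.too_fast}, slow (>3 SD): {report.too_slow}")
    out = RESULTS / "exclusion_reports.json"
    out.write_text(json.dumps(reports, indent=2) + "\n")
    print(f"wrote {out.name}")


if __name__ == "__main__":
    main()
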