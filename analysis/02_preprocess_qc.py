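#!/usr/bin/env python
"""Preprocess the cohort and tabulate artifact rejection.

Re-references, filters (1-48 Hz zero phase), segments 4 s epochs and
applies the automatic rejection rules (detection on unfiltered epochs).
Writes per-subject retained-trial counts to results/preprocessing_qc.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from mieeg import io as mio
from mieeg.study import StudyConfig, prepare_subject

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    cohort_dir = ROOT / "scratch" / "cohort"
    recordings = sorted(cohort_dir.glob("*.npy"))
    if not recordings:
        print("run 01_simulate_cohort.py first", file=sys.stderr)
        return 1
    config = StudyConfig(seed=0)
    rows = []
    for path in recordings:
        rec = mio.read_recording_npy(path.with_suffix(""))
        trials = prepare_subject(rec, config)
        counts = trials.counts_per_condition()
        rejected = [e for e in trials.rejected_log if e["reason"]]
        rows.append({
            "subject": rec.subject_id, "group": rec.group_tag,
            "retained_imagery": counts["imagery"],
            "retained_rest": counts["rest"],
            "rejected": len(rejected),
            "rules": ";".join(sorted({e["reason"] for e in rejected})) or "-",
        })
    qc = pd.DataFrame(rows)
    qc.to_csv(ROOT / "results" / "preprocessing_qc.tsv", sep="\t", index=False)
    print(qc.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
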