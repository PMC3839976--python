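#!/usr/bin/env python
"""Coherence and power-spectrum condition-difference maps.

Pooled (all-trials) coherence per condition, compared pair-by-pair and
bin-by-bin with the Fisher r-to-z two-sample statistic; per pair x bin,
the number of subjects significant after within-subject FDR, on the
13-electrode display subset.  Also the cohort mean/SD of the
rest-minus-imagery power difference per channel.  Tables to results/.
"""

import sys
import warnings
from pathlib import Path

from mieeg import cohstats, io as mio
from mieeg.study import StudyConfig, prepare_subject

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    warnings.filterwarnings("ignore")
    cohort_dir = ROOT / "scratch" / "cohort"
    recordings = sorted(cohort_dir.glob("*.npy"))
    if not recordings:
        print("run 01_simulate_cohort.py first", file=sys.stderr)
        return 1
    config = StudyConfig(seed=0)
    comparisons, power = {"responsive": [], "null": []}, []
    for path in recordings:
        rec = mio.read_recording_npy(path.with_suffix(""))
        trials = prepare_subject(rec, config)
        comparisons[rec.group_tag].append(
            cohstats.compare_subject_coherence(trials))
        power.append(cohstats.subject_power_difference(trials))
    for group, comps in comparisons.items():
        if not comps:
            continue
        counts = cohstats.subject_significance_counts(comps)
        counts.to_csv(ROOT / "results" / f"coherence_counts_{group}.tsv",
                      sep="\t", index=False)
        hot = counts[counts.n_significant > 0]
        print(f"{group}: {len(hot)} significant pair x bin cells "
              f"(of {len(counts)}); top pairs:")
        if not hot.empty:
            top = (hot.groupby(["channel_a", "channel_b"]).n_significant
                   .sum().sort_values(ascending=False).head(5))
            print(top.to_string())
    pooled = cohstats.cohort_power_difference(power)
    pooled.to_csv(ROOT / "results" / "power_difference.tsv", sep="\t",
                  index=False)
    c3 = pooled[(pooled.channel == "C3") & (pooled.group == "responsive")]
    print("\nC3 rest-imagery power difference (responsive group):")
    print(c3[["freq_hz", "mean_diff", "sd_diff"]].to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
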