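#!/usr/bin/env python
"""Classify the cohort: features x classifiers with LOOCV.

Runs a representative eight-feature battery (one from each family plus
the two spectral work-horses) under all four classifiers, attaches the
proportional-chance statistics, and writes the per-subject results to
results/classification.tsv.
"""

import sys
import warnings
from pathlib import Path

from mieeg import chance, io as mio
from mieeg.classify import DEFAULT_CLASSIFIERS, loocv
from mieeg.features.registry import extract_feature_matrix
from mieeg.study import StudyConfig, prepare_subject

ROOT = Path(__file__).resolve().parents[1]
FEATURES = (
    "hjorth_activity", "brainrate", "wackermann_omega", "hurst",
    "fft", "coherence", "apen", "shannon_spacing",
)


def main() -> int:
    warnings.filterwarnings("ignore")
    cohort_dir = ROOT / "scratch" / "cohort"
    recordings = sorted(cohort_dir.glob("*.npy"))
    if not recordings:
        print("run 01_simulate_cohort.py first", file=sys.stderr)
        return 1
    config = StudyConfig(seed=0)
    results = []
    for path in recordings:
        rec = mio.read_recording_npy(path.with_suffix(""))
        trials = prepare_subject(rec, config)
        for feat in FEATURES:
            fm = extract_feature_matrix(trials, feat)
            for spec in DEFAULT_CLASSIFIERS:
                results.append(loocv(fm, spec))
        print(f"{rec.subject_id}: done")
    chance.attach_chance_stats(results)
    mio.write_results_table(results, ROOT / "results" / "classification.tsv")
    ok = [r for r in results if not r.failed]
    print(f"\n{len(results)} results ({len(results) - len(ok)} failed)")
    for feat in FEATURES:
        accs = [r.accuracy for r in ok if r.feature_name == feat
                and r.classifier == "svm_linear"
                and r.group_tag == "responsive"]
        if accs:
            print(f"  {feat:>18} SVM responsive mean acc: "
                  f"{sum(accs) / len(accs):.3f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
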