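#!/usr/bin/env python
"""Group summaries, above-chance counts and comparison tables.

From results/classification.tsv: per group x feature x classifier
accuracy summaries (mean/SD/range, mean p, mean IOCC), above-chance
counts with and without FDR correction, classifier-vs-classifier
Wilcoxon tests on per-feature counts, and feature-vs-rest Wilcoxon
comparisons for the SVM.  Everything lands in results/.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

from mieeg import chance
from mieeg.classify import ClassificationResult

ROOT = Path(__file__).resolve().parents[1]


def load_results(path: Path) -> list[ClassificationResult]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(ClassificationResult(
            feature_name=r.feature, classifier=r.classifier,
            subject_id=r.subject, group_tag=r.group,
            n_correct=int(r.n_correct), n_total=int(r.N),
            n1=int(r.n1), n2=int(r.n2), failed=bool(r.failed),
            reason="" if pd.isna(r.reason) else str(r.reason),
            cpro=r.cpro, z=r.z, p=r.p, iocc=r.iocc))
    return out


def main() -> int:
    warnings.filterwarnings("ignore")
    table = ROOT / "results" / "classification.tsv"
    if not table.exists():
        print("run 03_classification_benchmark.py first", file=sys.stderr)
        return 1
    results = load_results(table)
    summary = chance.summarize_group(results)
    summary.to_csv(ROOT / "results" / "group_summary.tsv", sep="\t",
                   index=False)
    clf_cmp = chance.compare_classifiers(summary)
    clf_cmp.to_csv(ROOT / "results" / "classifier_comparisons.tsv", sep="\t",
                   index=False)
    feat_cmp = chance.compare_features(summary, classifier="svm_linear")
    for name, df in feat_cmp.items():
        df.to_csv(ROOT / "results" / f"feature_comparisons_{name}.tsv",
                  sep="\t", index=False)
    show = summary[summary.classifier == "svm_linear"][
        ["group", "feature", "mean_acc", "sd_acc", "range_acc",
         "mean_iocc", "n_above_unc", "n_above_fdr"]]
    print(show.to_string(index=False))
    return 0


if __name__ == "__main__":
    sys.exit(main())
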