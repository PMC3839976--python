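"""Calibration and recovery benchmarks run on synthetic cohorts.

Two standard experiments over the study pipeline:

* ``null_calibration`` — a cohort of null subjects (no ERD, no coupling)
  classified with a reduced feature battery; under the null, the
  above-chance rate per feature x classifier should match the nominal
  test level and FDR correction should remove essentially all discoveries.
* ``signal_recovery`` — a cohort of responsive subjects; the spectral
  features (binned FFT power, coherence) with the linear SVM should
  detect command-following in nearly every subject, with coherence at
  least as accurate as FFT under the coupled-effect generator.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import chance
from .classify import ClassifierSpec, loocv
from .features.registry import extract_feature_matrix
from .study import StudyConfig, prepare_subject
from .synth import EffectSpec, generate_cohort

#: Reduced battery for calibration runs: one time-domain, one spectral,
#: one connectivity and one entropy feature.
CALIBRATION_FEATURES = ("hjorth_activity", "fft", "coherence", "apen")
CALIBRATION_CLASSIFIERS = (
    ClassifierSpec(method="knn", k=3),
    ClassifierSpec(method="svm_linear"),
)


def _classify_cohort(
    recordings,
    features,
    classifiers,
    alpha: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    config = StudyConfig(seed=0)
    results = []
    for rec in recordings:
        trials = prepare_subject(rec, config)
        for feat in features:
            fm = extract_feature_matrix(trials, feat)
            for spec in classifiers:
                results.append(loocv(fm, spec))
    chance.attach_chance_stats(results)
    unc = chance.above_chance_mask(results, corrected=False, alpha=alpha)
    cor = chance.above_chance_mask(results, corrected=True, q=q)
    return pd.DataFrame([{
        "subject": r.subject_id, "group": r.group_tag,
        "feature": r.feature_name, "classifier": r.classifier,
        "accuracy": r.accuracy, "p": r.p, "iocc": r.iocc,
        "failed": r.failed, "above_unc": bool(u), "above_fdr": bool(c),
    } for r, u, c in zip(results, unc, cor)])


def null_calibration(
    n_subjects: int = 20,
    seed: int = 2025,
    features=CALIBRATION_FEATURES,
    classifiers=CALIBRATION_CLASSIFIERS,
) -> pd.DataFrame:
    """Classify a null cohort; returns one row per subject/feature/classifier."""
    spec = EffectSpec(erd_depth=0.0, coh_gain=0.0)
    cohort = generate_cohort(0, n_subjects, spec, seed=seed)
    return _classify_cohort(cohort, features, classifiers)


def signal_recovery(
    n_subjects: int = 10,
    seed: int = 2025,
    erd_depth: float = 0.4,
    coh_gain: float = 0.3,
    features=("fft", "coherence"),
    classifiers=(ClassifierSpec(method="svm_linear"),),
) -> pd.DataFrame:
    """Classify a responsive cohort with the two spectral features."""
    spec = EffectSpec(erd_depth=erd_depth, coh_gain=coh_gain)
    cohort = generate_cohort(n_subjects, 0, spec, seed=seed)
    return _classify_cohort(cohort, features, classifiers)


def false_positive_fractions(calibration: pd.DataFrame) -> pd.DataFrame:
    """Per feature x classifier: fraction of subjects above chance."""
    ok = calibration[~calibration.failed]
    return (
        ok.groupby(["feature", "classifier"])
        .agg(n=("above_unc", "size"),
             fraction_unc=("above_unc", "mean"),
             n_fdr=("above_fdr", "sum"))
        .reset_index()
    )
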