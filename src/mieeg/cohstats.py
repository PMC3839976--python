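"""Condition-difference maps: pooled coherence compared via Fisher's
r-to-z, per-subject significance counting, and power-spectrum difference
summaries.

Coherence is pooled over all trials of a condition (cross-spectra
averaged across every Welch segment of every trial) rather than averaged
over per-trial estimates, which strongly reduces the estimator's bias.
The pooled coherences of the two conditions are compared per channel pair
and frequency bin with the classical two-correlation z-test on
Fisher-transformed values, using the total Welch segment counts as the
effective sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chance import fdr_bh
from .features.binning import FrequencyBinning, default_binning
from .features.spectral import msc_from_csd, welch_csd_matrix
from .montage import DISPLAY_SUBSET_13
from .preprocess import TrialSet

_MSC_CLIP = 1.0 - 1e-12


@dataclass
class CoherenceComparison:
    """Pair x frequency-bin condition comparison for one subject.

    ``z_imagery``/``z_rest`` are Fisher-transformed coherence magnitudes;
    ``z_diff`` is the two-sample comparison statistic (antisymmetric under
    condition swap); ``fdr_significant`` applies BH over the within-subject
    family of all pairs x bins.
    """

    pair_labels: list[tuple[str, str]]
    bin_centers: np.ndarray
    msc_imagery: np.ndarray
    msc_rest: np.ndarray
    z_imagery: np.ndarray
    z_rest: np.ndarray
    z_diff: np.ndarray
    p: np.ndarray
    fdr_significant: np.ndarray
    n_imagery: int
    n_rest: int
    subject_id: str = "S00"
    group_tag: str = "responsive"


def pooled_coherence(
    trials: TrialSet,
    condition: str,
    binning: FrequencyBinning | None = None,
) -> tuple[np.ndarray, list[tuple[str, str]], int]:
    """Pooled magnitude-squared coherence over all trials of a condition.

    Returns (msc, pair_labels, n_segments) with msc of shape
    (n_pairs, n_bins) and n_segments the total number of Welch segments
    pooled (trials x segments per trial).
    """
    binning = binning or default_binning()
    idx = np.flatnonzero(trials.condition_mask(condition))
    if idx.size < 2:
        raise ValueError(f"need >= 2 trials of condition {condition!r}")
    acc = None
    n_total = 0
    freqs = None
    for i in idx:
        freqs, s, n_seg = welch_csd_matrix(trials.epochs[i], trials.rate)
        acc = s * n_seg if acc is None else acc + s * n_seg
        n_total += n_seg
    msc = msc_from_csd(acc / n_total)
    iu = np.triu_indices(msc.shape[0], k=1)
    labels = [
        (trials.channel_labels[a], trials.channel_labels[b])
        for a, b in zip(*iu)
    ]
    return binning.bin_average(freqs, msc[iu]), labels, n_total


def compare_coherence(
    msc_1: np.ndarray,
    msc_2: np.ndarray,
    n_1: int,
    n_2: int,
    fisher_on_msc: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample comparison of pooled coherences via Fisher's r-to-z.

    z_i = atanh(sqrt(msc_i)) (the coherence magnitude is the correlation
    analog; ``fisher_on_msc`` transforms the squared coherence instead),
    Z = (z_1 - z_2) / sqrt(1/(n_1-3) + 1/(n_2-3)), two-sided normal p.
    Coherences of exactly 1 are clipped just below 1.
    """
    if n_1 <= 3 or n_2 <= 3:
        raise ValueError("effective sample sizes must exceed 3")
    a = np.clip(np.asarray(msc_1, dtype=np.float64), 0.0, _MSC_CLIP)
    b = np.clip(np.asarray(msc_2, dtype=np.float64), 0.0, _MSC_CLIP)
    if not fisher_on_msc:
        a, b = np.sqrt(a), np.sqrt(b)
    z1 = np.arctanh(a)
    z2 = np.arctanh(b)
    se = np.sqrt(1.0 / (n_1 - 3) + 1.0 / (n_2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def compare_subject_coherence(
    trials: TrialSet,
    binning: FrequencyBinning | None = None,
    q: float = 0.05,
    fisher_on_msc: bool = False,
) -> CoherenceComparison:
    """Full imagery-vs-rest coherence comparison for one subject."""
    binning = binning or default_binning()
    msc_im, labels, n_im = pooled_coherence(trials, "imagery", binning)
    msc_re, _, n_re = pooled_coherence(trials, "rest", binning)
    z, p = compare_coherence(msc_im, msc_re, n_im, n_re,
                             fisher_on_msc=fisher_on_msc)
    finite = np.isfinite(p.ravel())
    rejected = np.zeros(p.size, dtype=bool)
    if finite.any():
        rej, _ = fdr_bh(p.ravel()[finite], q=q)
        rejected[np.flatnonzero(finite)] = rej
    a = np.clip(msc_im, 0.0, _MSC_CLIP)
    b = np.clip(msc_re, 0.0, _MSC_CLIP)
    if not fisher_on_msc:
        a, b = np.sqrt(a), np.sqrt(b)
    return CoherenceComparison(
        pair_labels=labels, bin_centers=binning.centers.copy(),
        msc_imagery=msc_im, msc_rest=msc_re,
        z_imagery=np.arctanh(a), z_rest=np.arctanh(b),
        z_diff=z, p=p, fdr_significant=rejected.reshape(p.shape),
        n_imagery=n_im, n_rest=n_re,
        subject_id=trials.subject_id, group_tag=trials.group_tag,
    )


def subject_significance_counts(
    comparisons: list[CoherenceComparison],
    subset: tuple[str, ...] | None = DISPLAY_SUBSET_13,
) -> pd.DataFrame:
    """Per pair x bin: number of subjects significant after within-subject FDR.

    ``subset`` restricts the output to pairs whose both electrodes lie in
    the display subset (None keeps all pairs).
    """
    if not comparisons:
        raise ValueError("no comparisons supplied")
    ref = comparisons[0]
    counts = np.zeros_like(ref.p, dtype=int)
    for comp in comparisons:
        if comp.pair_labels != ref.pair_labels:
            raise ValueError("comparisons have mismatched pair sets")
        counts += comp.fdr_significant.astype(int)
    rows = []
    keep = set(subset) if subset is not None else None
    for i, (a, b) in enumerate(ref.pair_labels):
        if keep is not None and (a not in keep or b not in keep):
            continue
        for j, center in enumerate(ref.bin_centers):
            rows.append({
                "channel_a": a, "channel_b": b,
                "freq_hz": float(center), "n_significant": int(counts[i, j]),
            })
    return pd.DataFrame(rows)


def subject_power_difference(
    trials: TrialSet,
    binning: FrequencyBinning | None = None,
    subset: tuple[str, ...] | None = DISPLAY_SUBSET_13,
) -> pd.DataFrame:
    """Per channel x bin mean (rest - imagery) binned power spectrum."""
    from .features.spectral import fft_binned_power

    binning = binning or default_binning()
    im = trials.condition_mask("imagery")
    re = trials.condition_mask("rest")
    if not im.any() or not re.any():
        raise ValueError("both conditions must be present")
    spectra = np.stack([
        fft_binned_power(ep, trials.rate, binning) for ep in trials.epochs
    ])
    diff = spectra[re].mean(axis=0) - spectra[im].mean(axis=0)
    rows = []
    for ci, ch in enumerate(trials.channel_labels):
        if subset is not None and ch not in subset:
            continue
        for j, center in enumerate(binning.centers):
            rows.append({
                "subject": trials.subject_id, "group": trials.group_tag,
                "channel": ch, "freq_hz": float(center),
                "rest_minus_imagery": float(diff[ci, j]),
            })
    return pd.DataFrame(rows)


def cohort_power_difference(per_subject: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-subject mean and SD of the per-channel power differences."""
    if not per_subject:
        raise ValueError("no subjects supplied")
    df = pd.concat(per_subject, ignore_index=True)
    return (
        df.groupby(["group", "channel", "freq_hz"])["rest_minus_imagery"]
        .agg(["mean", "std", "count"]).reset_index()
        .rename(columns={"mean": "mean_diff", "std": "sd_diff",
                         "count": "n_subjects"})
    )
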