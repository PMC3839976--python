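"""Above-chance evaluation: proportional chance criterion, z-statistic,
improvement-over-chance effect size (IOCC), Benjamini-Hochberg FDR,
above-chance counting, group summaries, Wilcoxon signed-rank comparisons
and advisory normality checks.

The chance level Cpro = (n1/N)^2 + (n2/N)^2 accounts for unequal retained
trial counts after artifact rejection; an accuracy counts as above chance
only when its (two-sided) p-value is small AND the IOCC is positive,
because the two-sided p is equally small for significantly below-chance
accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassificationResult

@dataclass(frozen=True)
class ChanceStats:
    """Chance-level statistics for one classification outcome."""

    cpro: float
    z: float
    p: float
    iocc: float
    n1: int
    n2: int
    n_correct: int

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2


def cpro(n1: int, n2: int) -> float:
    """Proportional chance criterion (n1/N)^2 + (n2/N)^2.

    0.5 at balance, 1.0 when one condition holds all trials.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("trial counts must be non-negative")
    n = n1 + n2
    if n == 0:
        raise ValueError("n1 + n2 must be positive")
    return (n1 / n) ** 2 + (n2 / n) ** 2


def improvement_z(
    n_correct: int, n_total: int, cpro_value: float, compat_pdf: bool = False
) -> tuple[float, float]:
    """z-statistic and p-value of the improvement over the chance criterion.

    z = (n_correct - N*Cpro) / sqrt(N*Cpro*(1-Cpro)); p is the two-sided
    standard-normal tail probability.  Below-chance accuracies give a
    negative z with a small p.  ``compat_pdf`` evaluates the normal
    density at z instead of the tail (a compatibility mode only).
    """
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must be within [0, N]")
    if not 0.0 < cpro_value < 1.0:
        raise ValueError("cpro must be strictly inside (0, 1)")
    z = (n_correct - n_total * cpro_value) / np.sqrt(
        n_total * cpro_value * (1.0 - cpro_value)
    )
    p = float(stats.norm.pdf(z)) if compat_pdf else float(
        2.0 * stats.norm.sf(abs(z))
    )
    return float(z), p


def iocc(accuracy: float, cpro_value: float) -> float:
    """Improvement over chance criterion (accuracy - Cpro) / (1 - Cpro)."""
    if cpro_value >= 1.0:
        raise ValueError("iocc undefined at cpro = 1")
    return (accuracy - cpro_value) / (1.0 - cpro_value)


def chance_stats(
    n_correct: int, n1: int, n2: int, compat_pdf: bool = False
) -> ChanceStats:
    c = cpro(n1, n2)
    z, p = improvement_z(n_correct, n1 + n2, c, compat_pdf=compat_pdf)
    return ChanceStats(
        cpro=c, z=z, p=p, iocc=iocc(n_correct / (n1 + n2), c),
        n1=n1, n2=n2, n_correct=n_correct,
    )


def attach_chance_stats(
    results: Iterable[ClassificationResult], compat_pdf: bool = False
) -> list[ClassificationResult]:
    """Fill cpro/z/p/iocc on every non-failed result, in place."""
    out = []
    for r in results:
        if not r.failed:
            s = chance_stats(r.n_correct, r.n1, r.n2, compat_pdf=compat_pdf)
            r.cpro, r.z, r.p, r.iocc = s.cpro, s.z, s.p, s.iocc
        out.append(r)
    return out


def fdr_bh(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up: (rejected mask, effective threshold).

    The effective threshold is the largest rejected p-value (0.0 if none
    is rejected).
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(sorted_p <= crit)
    if below.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    k = below[-1]
    threshold = float(sorted_p[k])
    return p <= threshold, threshold


def above_chance_mask(
    results: Sequence[ClassificationResult],
    corrected: bool,
    alpha: float = 0.05,
    q: float = 0.05,
) -> np.ndarray:
    """Above-chance indicator per result; failed results are never counted.

    Uncorrected: p < alpha and iocc > 0.  Corrected: BH step-up over the
    family of all non-failed results supplied, and iocc > 0.
    """
    ok = np.array([not r.failed for r in results])
    mask = np.zeros(len(results), dtype=bool)
    if not ok.any():
        return mask
    ps = np.array([r.p for r in results])[ok]
    ioccs = np.array([r.iocc for r in results])[ok]
    if corrected:
        rejected, _ = fdr_bh(ps, q=q)
    else:
        rejected = ps < alpha
    mask[np.flatnonzero(ok)] = rejected & (ioccs > 0)
    return mask


def count_above_chance(
    results: Sequence[ClassificationResult],
    corrected: bool,
    alpha: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Counts of above-chance subjects per group x feature x classifier."""
    mask = above_chance_mask(results, corrected, alpha=alpha, q=q)
    rows = [
        {
            "group": r.group_tag, "feature": r.feature_name,
            "classifier": r.classifier, "above": bool(m),
        }
        for r, m in zip(results, mask)
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["group", "feature", "classifier"])["above"]
        .sum().rename("count").reset_index()
    )


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test outcome (exact enumeration or normal approximation)."""

    statistic: float  # W+: rank sum of positive differences
    z: float | None
    p: float
    rank_sum: float
    n_used: int
    method: str


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    reference: float = 0.0,
    exact_limit: int = 25,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test, paired or one-sample against a reference.

    Zero differences are dropped; |differences| are ranked with mid-ranks
    for ties.  For n <= ``exact_limit`` the null distribution of W+ is
    enumerated exactly (all 2^n sign patterns, via a convolution over the
    doubled ranks); above that, a normal approximation with continuity
    correction and tie-corrected variance is used.  All differences zero
    gives the degenerate p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    d = x - (np.asarray(y, dtype=np.float64) if y is not None else reference)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, None, 1.0, 0.0, 0, "degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_limit:
        p = _exact_signed_rank_p(ranks, w_pos)
        return WilcoxonResult(w_pos, None, p, w_pos, n, "exact")
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(w_pos, None, 1.0, w_pos, n, "degenerate")
    delta = w_pos - mean
    cc = 0.5 * np.sign(delta)
    z = (delta - cc) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w_pos, float(z), min(p, 1.0), w_pos, n, "normal")


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p for W+ by convolution over doubled (integer) ranks."""
    doubled = np.round(2 * ranks).astype(int)
    total = doubled.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_pos))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def summarize_group(
    results: Sequence[ClassificationResult],
    alpha: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per group x feature x classifier: accuracy mean/SD/range, mean p,
    mean IOCC, above-chance counts (uncorrected and FDR), failure count.

    Failed results are excluded from every average; the FDR family is the
    whole set of non-failed results supplied.
    """
    if not results:
        raise ValueError("no results to summarize")
    mask_unc = above_chance_mask(results, corrected=False, alpha=alpha, q=q)
    mask_fdr = above_chance_mask(results, corrected=True, alpha=alpha, q=q)
    rows = []
    for r, mu, mf in zip(results, mask_unc, mask_fdr):
        rows.append({
            "group": r.group_tag, "feature": r.feature_name,
            "classifier": r.classifier, "subject": r.subject_id,
            "failed": r.failed, "accuracy": r.accuracy, "p": r.p,
            "iocc": r.iocc, "above_unc": bool(mu), "above_fdr": bool(mf),
        })
    df = pd.DataFrame(rows)
    ok = df[~df.failed]
    if ok.empty:
        raise ValueError("all supplied results failed")

    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "n": len(g), "mean_acc": g.accuracy.mean(),
            "sd_acc": g.accuracy.std(ddof=1) if len(g) > 1 else 0.0,
            "range_acc": g.accuracy.max() - g.accuracy.min(),
            "mean_p": g.p.mean(), "mean_iocc": g.iocc.mean(),
            "n_above_unc": int(g.above_unc.sum()),
            "n_above_fdr": int(g.above_fdr.sum()),
        })

    summary = (
        ok.groupby(["group", "feature", "classifier"])
        .apply(agg, include_groups=False).reset_index()
    )
    failures = (
        df.groupby(["group", "feature", "classifier"])["failed"]
        .sum().rename("n_failed").reset_index()
    )
    return summary.merge(failures, on=["group", "feature", "classifier"])


def compare_classifiers(
    summary: pd.DataFrame, q: float = 0.05
) -> pd.DataFrame:
    """Pairwise classifier comparison on per-feature above-chance counts.

    For each group and each classifier pair, a paired Wilcoxon signed-rank
    test over the per-feature counts, separately for the uncorrected and
    the FDR-corrected counts; each (group x correction) family is
    BH-corrected.
    """
    classifiers = sorted(summary.classifier.unique())
    if len(classifiers) < 2:
        raise ValueError("need >= 2 classifiers to compare")
    rows = []
    for group, gdf in summary.groupby("group"):
        for col, corrected in (("n_above_unc", False), ("n_above_fdr", True)):
            pivot = gdf.pivot_table(
                index="feature", columns="classifier", values=col
            )
            for i, a in enumerate(classifiers):
                for b in classifiers[i + 1:]:
                    res = wilcoxon_signed_rank(pivot[a].values, pivot[b].values)
                    rows.append({
                        "group": group, "corrected_counts": corrected,
                        "classifier_a": a, "classifier_b": b,
                        "statistic": res.statistic, "z": res.z, "p": res.p,
                        "rank_sum": res.rank_sum, "method": res.method,
                        "mean_count_a": pivot[a].mean(),
                        "mean_count_b": pivot[b].mean(),
                    })
    out = pd.DataFrame(rows)
    for (_, _), idx in out.groupby(["group", "corrected_counts"]).groups.items():
        rej, _thr = fdr_bh(out.loc[idx, "p"].values, q=q)
        out.loc[idx, "significant_fdr"] = rej
    return out


def compare_features(
    summary: pd.DataFrame, classifier: str = "svm_linear", q: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Each feature vs the pooled other features, for one classifier.

    Two families, each BH-corrected as a whole: (a) one-sample Wilcoxon on
    mean accuracy, SD and range (n_groups x n_features x 3 comparisons);
    (b) the same on above-chance counts, separately for the uncorrected
    and FDR-corrected counts (n_groups x n_features x 2 comparisons).
    """
    sub = summary[summary.classifier == classifier]
    features = sorted(sub.feature.unique())
    if len(features) < 2:
        raise ValueError("need >= 2 features to compare")
    metric_rows, count_rows = [], []
    for group, gdf in sub.groupby("group"):
        gdf = gdf.set_index("feature")
        for feat in features:
            others = [f for f in features if f != feat and f in gdf.index]
            if feat not in gdf.index or not others:
                continue
            for metric in ("mean_acc", "sd_acc", "range_acc"):
                res = wilcoxon_signed_rank(
                    gdf.loc[others, metric].values,
                    reference=float(gdf.loc[feat, metric]),
                )
                metric_rows.append({
                    "group": group, "feature": feat, "metric": metric,
                    "value": float(gdf.loc[feat, metric]),
                    "others_median": float(gdf.loc[others, metric].median()),
                    "p": res.p, "method": res.method,
                })
            for col in ("n_above_unc", "n_above_fdr"):
                res = wilcoxon_signed_rank(
                    gdf.loc[others, col].values.astype(float),
                    reference=float(gdf.loc[feat, col]),
                )
                count_rows.append({
                    "group": group, "feature": feat, "count_kind": col,
                    "value": float(gdf.loc[feat, col]),
                    "others_median": float(gdf.loc[others, col].median()),
                    "p": res.p, "method": res.method,
                })
    metrics = pd.DataFrame(metric_rows)
    counts = pd.DataFrame(count_rows)
    for df in (metrics, counts):
        if not df.empty:
            rej, thr = fdr_bh(df["p"].values, q=q)
            df["significant_fdr"] = rej
            df["family_size"] = len(df)
            df["fdr_threshold"] = thr
    return {"metrics": metrics, "counts": counts}


@dataclass(frozen=True)
class NormalityCheck:
    chi2_p: float
    lilliefors_p: float
    degenerate: bool


def normality_check(values: Sequence[float]) -> NormalityCheck:
    """Advisory normality diagnostics: chi-square GOF and Lilliefors.

    The chi-square test bins the sample against a fitted normal (bins
    pooled to expected counts >= 5, dof reduced by the 2 fitted
    parameters); Lilliefors comes from statsmodels.  Never gates the
    pipeline.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 8:
        raise ValueError("normality_check needs n >= 8")
    if x.std() == 0:
        return NormalityCheck(float("nan"), float("nan"), True)
    from statsmodels.stats.diagnostic import lilliefors as _lilliefors

    _, lf_p = _lilliefors(x, dist="norm")
    mu, sd = x.mean(), x.std(ddof=1)
    n_bins = max(4, int(np.ceil(np.sqrt(x.size))))
    qs = np.linspace(0, 1, n_bins + 1)
    edges = stats.norm.ppf(qs[1:-1], loc=mu, scale=sd)
    observed = np.histogram(x, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
    expected = np.full(n_bins, x.size / n_bins)
    # pool adjacent bins until every expected count is >= 5
    while expected.size > 3 and expected.min() < 5:
        i = int(np.argmin(expected))
        j = i + 1 if i + 1 < expected.size else i - 1
        expected[j] += expected[i]
        observed[j] += observed[i]
        expected = np.delete(expected, i)
        observed = np.delete(observed, i)
    dof = max(1, expected.size - 1 - 2)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    chi2_p = float(stats.chi2.sf(chi2, dof))
    return NormalityCheck(chi2_p, float(lf_p), False)
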