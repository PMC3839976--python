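"""Chance statistics: Cpro, improvement z, IOCC, BH-FDR (vs brute
force), Wilcoxon signed-rank (vs exhaustive enumeration), counting,
summaries, comparisons, normality diagnostics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mieeg.chance import (
    chance_stats,
    compare_classifiers,
    compare_features,
    count_above_chance,
    cpro,
    fdr_bh,
    improvement_z,
    iocc,
    normality_check,
    summarize_group,
    wilcoxon_signed_rank,
)
from mieeg.classify import ClassificationResult


def make_result(subject, feature, classifier, n_correct, n1=24, n2=24,
                group="responsive", failed=False) -> ClassificationResult:
    return ClassificationResult(
        feature_name=feature, classifier=classifier, subject_id=subject,
        group_tag=group, n_correct=n_correct, n_total=n1 + n2, n1=n1, n2=n2,
        failed=failed, reason="x" if failed else "")


class TestCpro:
    def test_balanced_is_half(self):
        assert cpro(24, 24) == 0.5

    def test_single_class_is_one(self):
        assert cpro(48, 0) == 1.0

    def test_unbalanced_arithmetic(self):
        assert cpro(30, 18) == pytest.approx(0.53125, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cpro(-1, 10)
        with pytest.raises(ValueError):
            cpro(0, 0)

    @given(st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=100, deadline=None)
    def test_minimized_at_balance_and_monotone_in_imbalance(self, n1, n2):
        if n1 + n2 == 0:
            return
        c = cpro(n1, n2)
        assert 0.5 <= c <= 1.0
        if n1 == n2:
            assert c == 0.5
        # moving one trial toward balance cannot increase cpro
        if n1 > n2:
            assert cpro(n1 - 1, n2 + 1) <= c


class TestImprovementZ:
    def test_anchored_example(self):
        z, p = improvement_z(36, 48, 0.5)
        assert z == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(2 * (1 - stats.norm.cdf(3.4641)), rel=1e-4)

    def test_chance_level_gives_zero(self):
        z, _ = improvement_z(24, 48, 0.5)
        assert z == 0.0

    def test_below_chance_negative_z_small_p(self):
        z, p = improvement_z(10, 48, 0.5)
        assert z < 0 and p < 0.001

    def test_compat_pdf_mode_returns_density(self):
        z, p = improvement_z(36, 48, 0.5, compat_pdf=True)
        assert p == pytest.approx(stats.norm.pdf(z), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            improvement_z(49, 48, 0.5)
        with pytest.raises(ValueError):
            improvement_z(10, 48, 1.0)

    def test_agrees_with_binomial_oracle_at_decision_boundary(self):
        """Normal-tail p vs two-sided mid-p exact binomial, factor <= 1.3.

        The mid-p variant halves the observed point's mass — the discrete
        analog of a normal approximation without continuity correction.
        """
        for n in range(20, 101):
            k = int(np.ceil(n * 0.5 + 1.96 * np.sqrt(n * 0.25)))
            _, p_norm = improvement_z(k, n, 0.5)
            pm = stats.binom.pmf(k, n, 0.5)
            mid_sf = stats.binom.sf(k - 1, n, 0.5) - 0.5 * pm
            p_mid = min(1.0, 2 * mid_sf)
            ratio = max(p_norm / p_mid, p_mid / p_norm)
            assert ratio <= 1.3

    def test_anchored_example_against_binomial_oracle(self):
        # the plain two-sided tail at 36/48 differs from the normal p by
        # a factor 1.35 (the tail counts the observed point's whole mass);
        # the mid-p tail, the discrete analog of the approximation, agrees
        # well within the 1.3 factor
        _, p_norm = improvement_z(36, 48, 0.5)
        pm = stats.binom.pmf(36, 48, 0.5)
        p_mid = 2 * (stats.binom.sf(35, 48, 0.5) - 0.5 * pm)
        assert max(p_norm / p_mid, p_mid / p_norm) <= 1.3


class TestIOCC:
    def test_identities(self):
        assert iocc(0.5, 0.5) == 0.0
        assert iocc(1.0, 0.5) == 1.0
        assert iocc(0.75, 0.5) == pytest.approx(0.5)
        assert iocc(0.25, 0.5) == pytest.approx(-0.5)

    def test_cpro_one_rejected(self):
        with pytest.raises(ValueError):
            iocc(1.0, 1.0)

    def test_sign_matches_z_sign(self):
        for n_correct in (10, 20, 24, 30, 40):
            s = chance_stats(n_correct, 24, 24)
            if s.z != 0:
                assert np.sign(s.iocc) == np.sign(s.z)


def fdr_bruteforce(p_values, q):
    """Literal step-up definition: largest k with p_(k) <= q k/m."""
    p = np.asarray(p_values)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k_star = rank
    mask = np.zeros(m, dtype=bool)
    if k_star:
        thr = np.sort(p)[k_star - 1]
        mask = p <= thr
    return mask


class TestFdrBH:
    def test_all_tiny_p_rejected(self):
        mask, thr = fdr_bh([0.001] * 10, q=0.05)
        assert mask.all() and thr == 0.001

    def test_stepup_ladder_all_rejected(self):
        mask, _ = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        assert mask.all()

    def test_none_rejected(self):
        mask, thr = fdr_bh([0.04, 0.2, 0.5], q=0.05)
        assert not mask.any() and thr == 0.0

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])

    def test_exhaustive_agreement_with_bruteforce_stepup(self):
        rng = np.random.default_rng(0)
        for m in range(1, 11):
            for _ in range(40):
                p = np.round(rng.uniform(0, 1, m), 3)
                mask, _ = fdr_bh(p, q=0.05)
                assert np.array_equal(mask, fdr_bruteforce(p, 0.05))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(0, 0.2, 50)
        mask, _ = fdr_bh(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(mask, ref)


def wilcoxon_bruteforce_p(d: np.ndarray) -> float:
    """Exact two-sided p by enumerating every sign assignment."""
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.array(ws)
    tol = 1e-9
    p = 2 * min((ws <= w_obs + tol).mean(), (ws >= w_obs - tol).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.p == 1.0 and res.method == "degenerate"

    def test_three_positive_differences_exact(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert res.p == pytest.approx(0.25)
        assert res.method == "exact"

    def test_exact_agrees_with_full_enumeration_n12(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            d = np.round(rng.standard_normal(12), 2)
            res = wilcoxon_signed_rank(d)
            assert res.p == pytest.approx(wilcoxon_bruteforce_p(d), abs=1e-9)

    def test_exact_handles_ties_via_midranks(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, -3.0, 3.0, 1.0])
        res = wilcoxon_signed_rank(d)
        assert res.p == pytest.approx(wilcoxon_bruteforce_p(d), abs=1e-9)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(40) + 0.4
        res = wilcoxon_signed_rank(d, exact_limit=25)
        ref = stats.wilcoxon(d, correction=True, method="approx").pvalue
        assert res.method == "normal"
        assert res.p == pytest.approx(ref, rel=0.05)


class TestCountsAndSummaries:
    def build_results(self):
        results = []
        for s in range(6):
            # one clearly above-chance subject, rest at chance
            n_correct = 46 if s == 0 else 25
            results.append(make_result(f"S{s}", "coherence", "svm_linear",
                                       n_correct))
        from mieeg.chance import attach_chance_stats

        return attach_chance_stats(results)

    def test_perfect_subject_counted_in_both_modes(self):
        results = self.build_results()
        unc = count_above_chance(results, corrected=False)
        fdr = count_above_chance(results, corrected=True)
        assert unc["count"].sum() == 1
        assert fdr["count"].sum() == 1

    def test_failed_results_excluded_from_family(self):
        results = self.build_results()
        results.append(make_result("S9", "coherence", "svm_linear", 48,
                                   failed=True))
        unc = count_above_chance(results, corrected=False)
        assert unc["count"].sum() == 1

    def test_summary_single_subject_has_zero_spread(self):
        from mieeg.chance import attach_chance_stats

        res = attach_chance_stats([make_result("S0", "fft", "dadf", 30)])
        df = summarize_group(res)
        row = df.iloc[0]
        assert row.sd_acc == 0.0 and row.range_acc == 0.0

    def test_summary_mean_and_range_arithmetic(self):
        from mieeg.chance import attach_chance_stats

        res = attach_chance_stats([
            make_result("S0", "fft", "dadf", 16, n1=20, n2=20),
            make_result("S1", "fft", "dadf", 24, n1=20, n2=20),
        ])
        df = summarize_group(res)
        row = df.iloc[0]
        assert row.mean_acc == pytest.approx(0.5)
        assert row.range_acc == pytest.approx(0.2)

    def test_summary_excludes_failed_and_reports_count(self):
        from mieeg.chance import attach_chance_stats

        res = attach_chance_stats([
            make_result("S0", "fft", "dadf", 40),
            make_result("S1", "fft", "dadf", 0, failed=True),
        ])
        df = summarize_group(res)
        assert df.iloc[0].n == 1 and df.iloc[0].n_failed == 1


class TestComparisons:
    def build_summary(self, planted: bool):
        from mieeg.chance import attach_chance_stats

        rng = np.random.default_rng(4)
        results = []
        features = [f"f{i}" for i in range(20)]
        for clf in ("knn_k1", "svm_linear"):
            for feat in features:
                for s in range(10):
                    strong = planted and feat == "f0"
                    n_correct = 46 if strong else int(
                        np.clip(rng.normal(24, 2), 15, 33))
                    results.append(
                        make_result(f"S{s}", feat, clf, n_correct))
        return summarize_group(attach_chance_stats(results))

    def test_identical_classifier_counts_give_p_one(self):
        summary = self.build_summary(planted=False)
        cmp_df = compare_classifiers(summary)
        # counts were generated identically sparse; ties dominate
        assert (cmp_df.p > 0.2).all()

    def test_planted_dominant_feature_flagged_after_fdr(self):
        summary = self.build_summary(planted=True)
        out = compare_features(summary, classifier="svm_linear")
        counts = out["counts"]
        f0 = counts[(counts.feature == "f0")
                    & (counts.count_kind == "n_above_unc")]
        assert bool(f0.significant_fdr.iloc[0])

    def test_family_sizes(self):
        summary = self.build_summary(planted=False)
        out = compare_features(summary, classifier="svm_linear")
        # one group: 20 features x 3 metrics; 20 features x 2 count kinds
        assert len(out["metrics"]) == 60
        assert len(out["counts"]) == 40
        assert (out["metrics"].family_size == 60).all()


class TestNormalityCheck:
    def test_gaussian_sample_passes_both(self):
        ok = 0
        for s in range(20):
            x = np.random.default_rng(s).standard_normal(500)
            res = normality_check(x)
            ok += (res.chi2_p > 0.05) and (res.lilliefors_p > 0.05)
        assert ok >= 16

    def test_uniform_sample_fails_lilliefors(self):
        bad = 0
        for s in range(20):
            x = np.random.default_rng(s).uniform(0, 1, 500)
            bad += normality_check(x).lilliefors_p < 0.05
        assert bad >= 18

    def test_constant_sample_degenerate(self):
        res = normality_check(np.full(20, 1.0))
        assert res.degenerate

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_check(np.arange(5.0))
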