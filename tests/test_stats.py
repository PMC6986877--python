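"""Statistical kernel: Fisher, proportion test, Wilcoxon, BH, moderated t."""

import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from glireg.stats import (
    ModeratedTPrior,
    Table2x2,
    bh_fdr,
    ddct_enrichment,
    estimate_prior,
    fisher_exact_2x2,
    fisher_exact_bruteforce,
    moderated_t,
    two_proportion_test,
    wilcoxon_rank_sum,
)


class TestFisherExact:
    def test_no_association_gives_one(self):
        assert fisher_exact_2x2(Table2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_small_table_full_enumeration(self):
        # hypergeometric enumeration over a in {0..4} gives 34/70
        assert fisher_exact_2x2(Table2x2(3, 1, 1, 3)) == pytest.approx(34 / 70)

    def test_promoter_proximity_table_matches_exact_references(self):
        """Exact two-sided Fisher p on the stable-vs-responsive promoter
        table (3544/2171 vs 91/258), pinned to the value confirmed by
        scipy.stats.fisher_exact and R fisher.test."""
        p = fisher_exact_2x2(Table2x2(3544, 2171, 91, 258))
        assert p == pytest.approx(9.094955112e-40, rel=1e-6)
        assert p == pytest.approx(
            sps.fisher_exact([[3544, 2171], [91, 258]]).pvalue, rel=1e-9
        )

    def test_one_sided_tails(self):
        t = Table2x2(8, 2, 2, 8)
        assert fisher_exact_2x2(t, "greater") == pytest.approx(
            sps.fisher_exact([[8, 2], [2, 8]], "greater").pvalue, rel=1e-9
        )
        assert fisher_exact_2x2(t, "less") == pytest.approx(
            sps.fisher_exact([[8, 2], [2, 8]], "less").pvalue, rel=1e-9
        )

    def test_doubling_rule_option(self):
        t = Table2x2(8, 2, 2, 8)
        expected = 2 * min(
            fisher_exact_2x2(t, "greater"), fisher_exact_2x2(t, "less")
        )
        assert fisher_exact_2x2(t, two_sided_rule="double") == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            Table2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            Table2x2(0, 0, 0, 0)


class TestTwoProportion:
    def test_hand_computed_z(self):
        # z = (0.8 - 0.1) / sqrt(0.25 * 0.2) = 3.1305 after Yates correction
        p = two_proportion_test(9, 10, 1, 10, sided="greater", continuity=True)
        assert p == pytest.approx(float(sps.norm.sf(3.130495)), rel=1e-4)

    def test_equal_proportions_not_significant(self):
        assert two_proportion_test(5, 10, 50, 100, sided="greater") >= 0.5

    def test_motif_presence_proportions(self):
        # 57.4% of 148 vs 39.5% of 5715, one-sided with continuity
        assert two_proportion_test(85, 148, 2257, 5715) == pytest.approx(
            8.00e-6, rel=0.05
        )

    def test_tail_complement_without_continuity(self):
        g = two_proportion_test(30, 50, 20, 60, "greater", continuity=False)
        l = two_proportion_test(30, 50, 20, 60, "less", continuity=False)
        assert g + l == pytest.approx(1.0)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            two_proportion_test(11, 10, 1, 10)


class TestWilcoxon:
    def test_exact_extreme_arrangement(self):
        # all x below all y: p = 1 / C(6,3) = 0.05 by rank enumeration
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "less") == pytest.approx(0.05)

    def test_identical_samples_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0] * 5
        assert wilcoxon_rank_sum(x, list(x), "greater") == pytest.approx(0.5)

    def test_exact_path_matches_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.permutation(12)[:5].astype(float)
            y = np.setdiff1d(np.arange(12), x)[:4].astype(float)
            ours = wilcoxon_rank_sum(x, y, "greater")
            ref = sps.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 35)
        ours = wilcoxon_rank_sum(x, y, "less")
        ref = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_null_pvalues_roughly_uniform(self):
        """Seeded simulation oracle: same-distribution samples give a
        uniform p-value distribution (Kolmogorov-Smirnov check)."""
        rng = np.random.default_rng(6)
        ps = [
            wilcoxon_rank_sum(rng.normal(size=50), rng.normal(size=50), "greater")
            for _ in range(300)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 1e-3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBhFdr:
    def test_step_up_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_order_preserved(self):
        p = [0.04, 0.001, 0.5, 0.02]
        q = bh_fdr(p)
        assert q[1] == min(q) and q[2] == max(q)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_q_dominates_p_and_monotone(self, pvals):
        q = bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestModeratedT:
    @staticmethod
    def _groups(seed=7, n=30, reps=(3, 3)):
        rng = np.random.default_rng(seed)
        return rng.normal(5, 1, (reps[0], n)), rng.normal(5, 1, (reps[1], n))

    def test_d0_zero_equals_classical_t(self):
        g1, g2 = self._groups()
        # with no prior weight the shrunken variance is the pooled variance
        t, df, p = moderated_t(g1, g2, prior=ModeratedTPrior(0.0, 1.0))
        ref = sps.ttest_ind(g1, g2, axis=0)
        assert np.allclose(t, ref.statistic)
        assert np.allclose(p, ref.pvalue)

    def test_shrinkage_formula_spot_value(self):
        prior = ModeratedTPrior(4.0, 1.0)
        # region built to have d_g = 2 and s_g^2 = 2 exactly
        g1 = np.array([[0.0], [2.0]])
        g2 = np.array([[0.0], [2.0]])
        t, df, p = moderated_t(g1, g2, prior=prior)
        # s~^2 = (4*1 + 2*2)/6 = 4/3; se = sqrt(4/3 * (1/2 + 1/2))
        assert t[0] == pytest.approx(0.0)
        assert df[0] == pytest.approx(6.0)
        g1_shift = g1 + 1.0
        t2, _, _ = moderated_t(g1_shift, g2, prior=prior)
        assert t2[0] == pytest.approx(1.0 / np.sqrt(4.0 / 3.0))

    def test_constant_variance_is_fixed_point(self):
        g1 = np.array([[0.0, 0.0], [2.0, 2.0], [1.0, 1.0]])
        g2 = g1 + 0.5
        prior = ModeratedTPrior(3.0, 1.0)
        t_a, _, _ = moderated_t(g1, g2, prior=prior)
        # identical s_g^2 == s0^2 for every region -> shrunken variance s0^2
        s_g = np.array([1.0, 1.0])
        s_tilde = (3.0 * 1.0 + 4 * s_g) / (3.0 + 4)
        assert np.allclose(s_tilde, 1.0)

    def test_large_d0_approaches_z_test(self):
        g1, g2 = self._groups(seed=8)
        t_inf, df_inf, p_inf = moderated_t(g1, g2, prior=ModeratedTPrior(np.inf, 1.0))
        t_big, df_big, p_big = moderated_t(g1, g2, prior=ModeratedTPrior(1e9, 1.0))
        assert np.allclose(t_inf, t_big, rtol=1e-4)
        assert np.allclose(p_inf, p_big, rtol=1e-3)

    def test_replicate_deficit_rejected(self):
        with pytest.raises(ValueError):
            moderated_t(np.ones((1, 5)), np.ones((2, 5)))

    def test_matches_limma_reference(self, tmp_path):
        """Dual-route check: prior estimation, t and p agree with the
        reference empirical-Bayes implementation in R (limma)."""
        rng = np.random.default_rng(42)
        n = 60
        scales = rng.gamma(2.0, 0.5, size=n)
        g1 = rng.normal(5, 1, size=(3, n)) * np.sqrt(scales)
        g2 = rng.normal(5, 1, size=(2, n)) * np.sqrt(scales)
        mat = tmp_path / "mat.tsv"
        np.savetxt(mat, np.vstack([g1, g2]).T, delimiter="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("{mat}"))
            design <- cbind(Intercept=1, Diff=c(1,1,1,0,0))
            fit <- eBayes(lmFit(x, design))
            cat(fit$df.prior, fit$s2.prior, "\\n")
            cat(fit$t[,"Diff"], "\\n")
            cat(fit$p.value[,"Diff"], "\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        lines = out.stdout.strip().splitlines()
        d0_ref, s0_ref = map(float, lines[0].split())
        t_ref = np.array(list(map(float, lines[1].split())))
        p_ref = np.array(list(map(float, lines[2].split())))

        s_sq = (((g1 - g1.mean(0)) ** 2).sum(0) + ((g2 - g2.mean(0)) ** 2).sum(0)) / 3
        prior = estimate_prior(s_sq, 3)
        t, df, p = moderated_t(g1, g2)
        assert prior.d0 == pytest.approx(d0_ref, rel=1e-5)
        assert prior.s0_sq == pytest.approx(s0_ref, rel=1e-5)
        assert np.allclose(t, t_ref, rtol=1e-5)
        assert np.allclose(p, p_ref, rtol=1e-5)


class TestDdct:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20.0, 20.0, 20.0, 20.0), 1.0),
            ((20.0, 21.0, 25.0, 25.0), 2.0),
            ((20.0, 24.0, 25.0, 26.0), 8.0),
        ],
    )
    def test_fold_enrichment(self, cts, expected):
        assert ddct_enrichment(*cts) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            ddct_enrichment(np.nan, 1.0, 1.0, 1.0)


def test_fisher_matches_bruteforce_sample():
    """Spot equivalence with the factorial enumeration oracle (the
    exhaustive N <= 12 sweep lives in the acceptance suite)."""
    rng = np.random.default_rng(9)
    for _ in range(25):
        a, b, c, d = rng.integers(0, 5, 4)
        if a + b + c + d == 0:
            continue
        t = Table2x2(int(a), int(b), int(c), int(d))
        for sided in ("two_sided", "greater", "less"):
            assert fisher_exact_2x2(t, sided) == pytest.approx(
                fisher_exact_bruteforce(t, sided), rel=1e-9
            )
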