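"""Statistics toolkit: worked examples, hand oracles, symmetry properties.

Cross-checks against external reference implementations (scipy, sklearn,
pingouin, statsmodels) live in the acceptance suite; here every expected
value is computed by hand or by an explicit brute-force oracle inside the
test.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from pasmri import stats as st


class TestChiSquare:
    def test_observed_equals_expected(self):
        res = st.chi_square([[5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # O = [[10, 20], [20, 10]]; margins 30/30, 30/30, N=60 -> E = 15 all
        # stat = 4 * (5^2 / 15) = 20/3
        res = st.chi_square([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20.0 / 3.0)
        assert res.df == 1

    def test_yates_subtracts_half(self):
        # same table with correction: 4 * (4.5^2 / 15) = 5.4
        res = st.chi_square([[10, 20], [20, 10]], continuity_correction=True)
        assert res.statistic == pytest.approx(4 * 4.5 ** 2 / 15.0)
        assert res.method == "yates-chi2"

    def test_yates_clamps_at_zero(self):
        # |O - E| = 0.25 < 0.5 in every cell -> statistic clamps to 0
        res = st.chi_square([[5, 4], [4, 5]], continuity_correction=True)
        assert res.statistic == 0.0

    def test_transpose_invariance(self):
        t = np.array([[1, 3, 2, 19], [5, 2, 1, 18], [0, 1, 0, 23]])
        assert st.chi_square(t).statistic == pytest.approx(
            st.chi_square(t.T).statistic)

    def test_rejects_degenerate_tables(self):
        with pytest.raises(ValueError):
            st.chi_square([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            st.chi_square([[1, 2, 3]])
        with pytest.raises(ValueError):
            st.chi_square([[1, 2, 3], [4, 5, 6]], continuity_correction=True)
        with pytest.raises(ValueError):
            st.chi_square([[1, -2], [3, 4]])


class TestSpearman:
    def test_strict_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert st.spearman(x, [10, 20, 30, 40, 50]).rho == pytest.approx(1.0)
        assert st.spearman(x, [50, 40, 30, 20, 10]).rho == pytest.approx(-1.0)

    def test_tied_example_against_brute_force_midranks(self):
        x = [1, 2, 2, 4]
        y = [10, 20, 30, 30]
        # mid-ranks: x -> 1, 2.5, 2.5, 4 ; y -> 1, 2, 3.5, 3.5
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 2.0, 3.5, 3.5])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert st.spearman(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_undefined(self):
        res = st.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.rho)
        assert "constant" in res.method

    def test_exact_permutation_small_n(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        res = st.spearman(x, y, method="exact")
        # brute force: enumerate all 720 permutations of y's ranks
        rx = np.arange(1.0, 7.0)
        rho_obs = np.corrcoef(rx, st._midranks(np.array(y, float)))[0, 1]
        count = sum(
            abs(np.corrcoef(rx, np.array(p))[0, 1]) >= abs(rho_obs) - 1e-12
            for p in itertools.permutations(range(1, 7)))
        assert res.p_value == pytest.approx(count / 720.0)
        assert res.rho == pytest.approx(rho_obs)

    @given(hst.lists(hst.integers(-5000, 5000), min_size=4, max_size=25, unique=True))
    def test_monotone_transform_preserves_rho_one(self, xs):
        x = np.asarray(xs, dtype=float) / 100.0
        y = np.exp(x / 50.0) + 3.0   # strictly increasing transform
        assert st.spearman(x, y).rho == pytest.approx(1.0)


class TestROC:
    def test_perfect_separation(self):
        res = st.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        res = st.roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_pair_counting_identity_worked_example(self):
        scores = [1, 2, 3, 4]
        labels = [0, 0, 1, 1]
        res = st.roc_auc(scores, labels)
        assert res.auc == pytest.approx(st.mann_whitney_auc(scores, labels))

    def test_curve_monotone_and_anchored(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        res = st.roc_auc(scores, labels)
        assert res.sensitivity[0] == res.fpr[0] == 0.0
        assert res.sensitivity[-1] == res.fpr[-1] == 1.0
        assert np.all(np.diff(res.sensitivity) >= 0)
        assert np.all(np.diff(res.fpr) >= 0)

    def test_mann_whitney_identity_random_instances(self, rng):
        for _ in range(50):
            n = rng.integers(6, 40)
            scores = rng.integers(0, 6, size=n).astype(float)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert st.roc_auc(scores, labels).auc == pytest.approx(
                st.mann_whitney_auc(scores, labels), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            st.roc_auc([1.0, 2.0], [1, 1])


class TestKappa:
    def test_identical_ratings(self):
        res = st.cohens_kappa([0, 1, 2, 0, 1], [0, 1, 2, 0, 1])
        assert res.value == pytest.approx(1.0)

    def test_chance_level_construction(self):
        # p_o = p_e = 0.5 by construction -> kappa = 0
        r1 = [0, 0, 1, 1]
        r2 = [0, 1, 0, 1]
        assert st.cohens_kappa(r1, r2).value == pytest.approx(0.0)

    def test_2x2_agreement_table_hand_oracle(self):
        # confusion [[20, 5], [10, 15]]: p_o = 0.7,
        # p_e = (25*30 + 25*20) / 50^2 = 0.5 -> kappa = 0.4
        r1 = [0] * 25 + [1] * 25
        r2 = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 15
        assert st.cohens_kappa(r1, r2).value == pytest.approx(0.4)

    def test_both_raters_constant_undefined(self):
        res = st.cohens_kappa([1, 1, 1], [1, 1, 1])
        assert np.isnan(res.value)
        assert "undefined" in res.note

    def test_weighted_variants_ordered(self):
        # adjacent disagreements on an ordinal scale are penalised less by
        # quadratic weights than by the unweighted coefficient
        r1 = [0, 0, 1, 1, 2, 2, 0, 1, 2, 2]
        r2 = [0, 1, 1, 2, 2, 1, 0, 1, 2, 0]
        ku = st.cohens_kappa(r1, r2).value
        kq = st.cohens_kappa(r1, r2, weights="quadratic").value
        assert kq != pytest.approx(ku)

    def test_symmetric_in_raters(self, rng):
        r1 = rng.integers(0, 3, 40)
        r2 = rng.integers(0, 3, 40)
        assert st.cohens_kappa(r1, r2).value == pytest.approx(
            st.cohens_kappa(r2, r1).value, abs=1e-12)


class TestICC:
    def test_perfect_agreement(self):
        y = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert st.icc(y).value == pytest.approx(1.0)

    def test_offset_penalised_by_absolute_agreement(self):
        base = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.0])
        y = np.column_stack([base, base + 10.0])
        res2 = st.icc(y, kind="icc2")
        res3 = st.icc(y, kind="icc3")
        assert res2.value < 0.1         # offset destroys absolute agreement
        assert res3.value == pytest.approx(1.0)  # consistency ignores it

    def test_worked_matrix_against_anova_decomposition(self):
        # independent oracle: explicit two-way ANOVA mean squares
        Y = np.array([[9.0, 2.0], [6.0, 1.0], [8.0, 4.0],
                      [7.0, 1.0], [10.0, 5.0], [6.0, 2.0]])
        n, k = Y.shape
        grand = Y.mean()
        msr = k * np.sum((Y.mean(1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((Y.mean(0) - grand) ** 2) / (k - 1)
        mse = (np.sum((Y - grand) ** 2)
               - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert st.icc(Y).value == pytest.approx(expected, abs=1e-12)

    def test_zero_between_subject_variance(self):
        y = np.array([[3.0, 4.0], [3.0, 4.0], [3.0, 4.0]])
        res = st.icc(y)
        assert res.value == 0.0
        assert "degenerate" in res.note


class TestKruskalWallis:
    def test_identical_observations(self):
        res = st.kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_three_group_hand_ranked(self):
        # groups [1,2],[3,4],[5,6]: rank means 1.5, 3.5, 5.5; no ties
        # H = 12/(6*7) * 2*((1.5-3.5)^2 + 0 + (5.5-3.5)^2) = 32/7
        res = st.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32.0 / 7.0)
        assert res.df == 2

    def test_two_groups_match_rank_sum_identity(self):
        # untied two-group H equals 12/(N(N+1)) (R1^2/n1 + R2^2/n2) - 3(N+1)
        g1 = [1.0, 4.0, 6.0, 7.0]
        g2 = [2.0, 3.0, 5.0, 8.0]
        pooled = np.array(g1 + g2)
        ranks = pooled.argsort().argsort() + 1.0
        R1, R2 = ranks[:4].sum(), ranks[4:].sum()
        N = 8
        H_formula = 12.0 / (N * (N + 1)) * (R1 ** 2 / 4 + R2 ** 2 / 4) - 3 * (N + 1)
        assert st.kruskal_wallis([g1, g2]).statistic == pytest.approx(H_formula)

    def test_two_groups_against_exact_permutation(self):
        """chi-square approximate p stays close to the exact permutation p
        on a small instance."""
        g1 = [1.0, 2.0, 3.0, 9.0]
        g2 = [4.0, 5.0, 7.0, 8.0]
        obs = st.kruskal_wallis([g1, g2]).statistic
        pooled = g1 + g2
        count = total = 0
        for idx in itertools.combinations(range(8), 4):
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(8) if i not in idx]
            h = st.kruskal_wallis([a, b]).statistic
            count += h >= obs - 1e-12
            total += 1
        p_exact = count / total
        p_approx = st.kruskal_wallis([g1, g2]).p_value
        assert abs(p_approx - p_exact) < 0.1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.kruskal_wallis([[1.0], []])


class TestAnova:
    def test_equal_group_means_give_zero_F(self):
        res = st.oneway_anova([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_textbook_decomposition(self):
        # groups [1,2,3],[2,3,4],[5,6,7]: grand mean 33/9 = 11/3
        # SSB = 3[(2-11/3)^2 + (3-11/3)^2 + (6-11/3)^2] = 26/3*3 = 26
        # each group SS within = 2 -> SSW = 6; F = (26/2)/(6/6) = 13
        res = st.oneway_anova([[1, 2, 3], [2, 3, 4], [5, 6, 7]])
        assert res.statistic == pytest.approx(13.0)

    def test_p_decreases_with_separation(self):
        base = [[1.0, 2.0, 3.0], [1.5, 2.5, 3.5]]
        ps = []
        for shift in (0.5, 2.0, 8.0):
            groups = [base[0], [x + shift for x in base[1]]]
            ps.append(st.oneway_anova(groups).p_value)
        assert ps[0] > ps[1] > ps[2]

    def test_zero_within_variance_unequal_means(self):
        res = st.oneway_anova([[2.0, 2.0], [3.0, 3.0]])
        assert res.p_value == 0.0
        assert "zero within-group variance" in res.note

    def test_all_identical(self):
        res = st.oneway_anova([[2.0, 2.0], [2.0, 2.0]])
        assert res.p_value == 1.0


class TestKSNormality:
    def test_statistic_on_five_points_by_hand(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        res = st.ks_normality(x)
        z = np.sort((x - x.mean()) / x.std(ddof=1))
        from scipy.stats import norm
        F = norm.cdf(z)
        i = np.arange(1, 6)
        D_hand = max((i / 5 - F).max(), (F - (i - 1) / 5).max())
        assert res.statistic == pytest.approx(D_hand, abs=1e-15)

    def test_rejection_rate_near_nominal_alpha(self, rng):
        """Sampling from the fitted family, the Lilliefors-corrected test
        rejects at close to the nominal 5% rate."""
        n_rep, n = 600, 80
        rejections = sum(
            st.ks_normality(rng.normal(3.0, 2.0, n)).p_value < 0.05
            for _ in range(n_rep))
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09   # 3 MC sds around 0.05

    def test_naive_p_anticonservative_vs_corrected(self, rng):
        x = rng.normal(size=60)
        corrected = st.ks_normality(x, corrected=True)
        naive = st.ks_normality(x, corrected=False)
        assert naive.p_value >= corrected.p_value - 0.3  # naive is inflated

    def test_power_against_heavy_tails(self, rng):
        rejections = sum(
            st.ks_normality(rng.standard_cauchy(200)).p_value < 0.05
            for _ in range(50))
        assert rejections >= 45

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.ks_normality([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            st.ks_normality([5.0] * 10)


class TestMidranks:
    @given(hst.lists(hst.integers(-5, 5), min_size=1, max_size=40))
    def test_midranks_sum_invariant(self, xs):
        r = st._midranks(np.asarray(xs, dtype=float))
        n = len(xs)
        assert r.sum() == pytest.approx(n * (n + 1) / 2)

    def test_tie_blocks_average(self):
        assert np.allclose(st._midranks(np.array([3.0, 1.0, 3.0])),
                           [2.5, 1.0, 2.5])
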