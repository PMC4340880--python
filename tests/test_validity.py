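"""Reliability and validity statistics."""

import numpy as np
import pytest

from macetools import (
    TwoByTwo,
    bland_altman,
    bonferroni,
    lmg_decomposition,
    odds_ratio,
    pearson_with_ci,
    reconstruct_counts,
    roc_auc,
    williams_test,
)


class TestBlandAltman:
    def test_identical_tests_are_repeatable(self, rng):
        x = rng.normal(50, 10, 40)
        ba = bland_altman(x, x)
        assert ba.mean_diff == 0.0
        assert ba.pct_within_limits == 100.0
        assert ba.p_value == 1.0 and ba.repeatable

    def test_constant_offset_detected(self, rng):
        x = rng.normal(50, 10, 60)
        ba = bland_altman(x, x + 5 + rng.normal(0, 0.1, 60))
        assert ba.mean_diff == pytest.approx(5.0, abs=0.1)
        assert ba.p_value < 1e-10 and not ba.repeatable

    def test_limits_symmetric_about_mean(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 0.5, 30)
        ba = bland_altman(x, y)
        lo, hi = ba.limits
        assert (lo + hi) / 2 == pytest.approx(ba.mean_diff)
        assert hi - ba.mean_diff == pytest.approx(2 * ba.sd_diff)

    def test_gaussian_coverage_near_95(self):
        # retest = truth + N(0, sigma) at n = 75: about 95.4% of the
        # differences fall inside +/- 2 SD on average
        rng = np.random.default_rng(22)
        pcts = [bland_altman(t := rng.normal(50, 10, 75),
                             t + rng.normal(0, 3, 75)).pct_within_limits
                for _ in range(300)]
        assert np.mean(pcts) == pytest.approx(95.4, abs=1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2])


class TestPearsonCi:
    def test_ci_brackets_known_correlation(self, rng):
        z = rng.standard_normal((2000, 2))
        y = 0.6 * z[:, 0] + np.sqrt(1 - 0.36) * z[:, 1]
        r, (lo, hi), df, p = pearson_with_ci(z[:, 0], y)
        assert lo < 0.6 < hi
        assert df == 1998
        assert p < 1e-10

    def test_needs_four_points(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 2, 3], [1, 2, 3])


class TestWilliams:
    def test_equal_correlations_give_zero(self):
        t, p = williams_test(0.4, 0.4, 0.3, 100)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_published_scale_comparison_magnitude(self):
        # instrument vs comparator correlations with a symptom scale
        # (0.44 vs 0.33, predictors correlated ~0.70, n = 1034): the
        # difference is strongly significant, t on the order of 5
        t, p = williams_test(0.44, 0.33, 0.698, 1034)
        assert 4.0 < t < 6.5
        assert p < 1e-4

    def test_type_i_error_calibrated(self):
        # trivariate normal null with equal correlations to the criterion
        rng = np.random.default_rng(21)
        C = np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.5], [0.3, 0.5, 1.0]])
        L = np.linalg.cholesky(C)
        rej = 0
        reps = 10_000
        for _ in range(reps):
            z = rng.standard_normal((60, 3)) @ L.T
            R = np.corrcoef(z, rowvar=False)
            _, p = williams_test(R[0, 1], R[0, 2], R[1, 2], 60)
            rej += p < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.01)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            williams_test(1.0, 0.3, 0.2, 50)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_independent_scores_near_half(self, rng):
        s = rng.normal(0, 1, 4000)
        y = rng.integers(0, 2, 4000)
        auc, (lo, hi) = roc_auc(s, y)
        assert auc == pytest.approx(0.5, abs=0.03)
        assert lo < 0.5 < hi

    def test_matches_all_pairs_oracle(self, rng):
        # concordant-pair fraction (+1/2 per tie) on small tied instances
        for _ in range(50):
            n = int(rng.integers(8, 25))
            s = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            pos = s[y == 1]
            neg = s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expected = wins / (pos.size * neg.size)
            assert roc_auc(s, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_reversed_scores_complement(self, rng):
        s = rng.normal(0, 1, 200)
        y = (s + rng.normal(0, 1, 200) > 0).astype(int)
        assert roc_auc(s, y)[0] + roc_auc(-s, y)[0] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestOddsRatio:
    def test_female_male_prevalence_reproductions(self):
        # prevalence rows reconstructed against group sizes 670 / 381;
        # the conditional-MLE estimate reproduces the printed ratios
        sa = reconstruct_counts(13.43, 670, 4.99, 381)
        assert (sa.a, sa.b, sa.c, sa.d) == (90, 580, 19, 362)
        res = odds_ratio(sa)
        assert res.conditional_or == pytest.approx(2.95, abs=0.01)
        assert res.sample_or == pytest.approx(2.96, abs=0.01)
        assert res.fisher_p < 1e-5

        bully = reconstruct_counts(10.15, 670, 25.20, 381)
        res = odds_ratio(bully)
        assert res.conditional_or == pytest.approx(0.33, abs=0.01)
        assert res.fisher_p < 1e-9

        neglect = reconstruct_counts(22.39, 670, 14.96, 381)
        res = odds_ratio(neglect)
        assert res.conditional_or == pytest.approx(1.64, abs=0.01)
        assert res.fisher_p < 0.01

    def test_exact_ci_matches_published_interval(self):
        res = odds_ratio(TwoByTwo(90, 580, 19, 362))
        assert res.ci_exact[0] == pytest.approx(1.75, abs=0.01)
        assert res.ci_exact[1] == pytest.approx(5.22, abs=0.01)

    def test_symmetric_table_is_null(self):
        res = odds_ratio(TwoByTwo(25, 25, 25, 25))
        assert res.sample_or == 1.0 and res.fisher_p == pytest.approx(1.0)

    def test_zero_cell_haldane_flag(self):
        res = odds_ratio(TwoByTwo(10, 20, 0, 30))
        assert res.haldane_corrected
        assert np.isfinite(res.sample_or)

    def test_fisher_p_transpose_invariant(self):
        p1 = odds_ratio(TwoByTwo(12, 5, 7, 19)).fisher_p
        p2 = odds_ratio(TwoByTwo(12, 7, 5, 19)).fisher_p
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_non_integer_reconstruction_warns(self):
        with pytest.warns(UserWarning, match="not within"):
            reconstruct_counts(10.0, 673, 5.0, 381)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)


class TestLmg:
    def test_orthogonal_regressors_get_univariate_r2(self, rng):
        X = rng.standard_normal((400, 3))
        Q, _ = np.linalg.qr(X - X.mean(0))  # exactly orthogonal columns
        y = Q @ [0.5, 0.3, 0.1] + rng.normal(0, 0.5, 400)
        lmg = lmg_decomposition(y, Q)
        for j in range(3):
            r = np.corrcoef(Q[:, j], y)[0, 1]
            assert lmg.shares[j] == pytest.approx(r**2, abs=1e-10)

    def test_matches_ordering_enumeration(self, rng):
        # p = 3: brute force over all 6 orderings of sequential increments
        from itertools import permutations

        X = rng.standard_normal((150, 3)) @ np.array(
            [[1, 0.4, 0.2], [0, 1, 0.4], [0, 0, 1]])
        y = X @ [1.0, 0.5, -0.3] + rng.normal(0, 1, 150)

        def r2(cols):
            if not cols:
                return 0.0
            A = np.column_stack([np.ones(len(y)), X[:, list(cols)]])
            resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            return 1 - resid.var() / y.var()

        brute = np.zeros(3)
        for order in permutations(range(3)):
            done = []
            for j in order:
                brute[j] += r2(done + [j]) - r2(done)
                done.append(j)
        brute /= 6
        lmg = lmg_decomposition(y, X)
        assert lmg.shares == pytest.approx(brute, abs=1e-12)

    def test_shares_sum_to_model_r2(self, rng):
        for _ in range(10):
            p = int(rng.integers(2, 6))
            X = rng.standard_normal((200, p))
            y = X @ rng.normal(0, 1, p) + rng.normal(0, 1, 200)
            lmg = lmg_decomposition(y, X)
            assert abs(lmg.shares.sum() - lmg.model_r2) < 1e-10
            assert np.all(lmg.shares >= -1e-12)

    def test_pure_noise_regressor_gets_nothing(self, rng):
        x1 = rng.standard_normal(5000)
        x2 = rng.standard_normal(5000)
        y = 2 * x1 + rng.normal(0, 1, 5000)
        lmg = lmg_decomposition(y, np.column_stack([x1, x2]), names=["sig", "noise"])
        assert lmg.shares[0] == pytest.approx(lmg.model_r2, abs=0.01)
        assert lmg.shares[1] < 0.01

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal(100)
        X = np.column_stack([x, 2 * x, rng.standard_normal(100)])
        with pytest.raises(ValueError, match="x1.*x2|rank"):
            lmg_decomposition(rng.standard_normal(100), X)

    def test_regressor_limit(self, rng):
        X = rng.standard_normal((40, 11))
        with pytest.raises(ValueError, match="10"):
            lmg_decomposition(rng.standard_normal(40), X)


def test_bonferroni_caps_at_one():
    adj = bonferroni([0.01, 0.4, 0.9], m=45)
    assert adj == pytest.approx([0.45, 1.0, 1.0])
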