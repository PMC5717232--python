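"""Statistical-layer tests with independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from streamselect.stats import (
    StatResult,
    align_rank,
    art_rm_anova,
    attach_fdr,
    fdr_adjust,
    linear_trend_slope,
    one_sample_ttest,
    signed_rank_test,
)


def brute_force_signed_rank_p(x, tail="greater"):
    """Enumerate all sign assignments of the ranked |differences|."""
    d = np.asarray(x, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array([np.sum(ranks[list(signs)])
                   for signs in itertools.product([False, True], repeat=n)
                   ], dtype=float)
    # signs select the "positive" subset
    ws = np.array([ranks[np.array(signs, dtype=bool)].sum()
                   for signs in itertools.product([0, 1], repeat=n)])
    if tail == "greater":
        return np.mean(ws >= w_obs - 1e-12), w_obs
    return np.mean(ws <= w_obs + 1e-12), w_obs


class TestSignedRank:
    def test_three_positive_values(self):
        """x = [1,2,3]: W = 6 and one-sided p = 1/8 by enumeration."""
        r = signed_rank_test([1.0, 2.0, 3.0], tail="greater")
        assert r.statistic == 6.0
        assert r.p_raw == pytest.approx(0.125)

    def test_matches_brute_force_enumeration(self):
        """Exact path agrees with full sign enumeration, ties and zeros
        included (W identical, p to machine precision)."""
        rng = np.random.default_rng(0)
        for _ in range(150):
            n = rng.integers(5, 13)
            x = np.round(rng.standard_normal(n) * 2, 1)  # induces ties/zeros
            if np.all(x == 0):
                continue
            for tail in ("greater", "less"):
                expected_p, expected_w = brute_force_signed_rank_p(x, tail)
                r = signed_rank_test(x, tail=tail)
                assert r.statistic == pytest.approx(expected_w)
                assert r.p_raw == pytest.approx(expected_p, abs=1e-12)

    def test_matches_scipy_exact_for_untied_data(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.standard_normal(12)
            ours = signed_rank_test(x, tail="greater").p_raw
            ref = scipy.stats.wilcoxon(x, alternative="greater",
                                       method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_boundary(self):
        """At n = 15 (last exact size) the tie-corrected normal
        approximation lands within 0.02 of the enumerated p."""
        rng = np.random.default_rng(2)
        for _ in range(40):
            x = rng.standard_normal(15) + 0.3
            exact = signed_rank_test(x, tail="greater").p_raw
            d = x[x != 0]
            ranks = scipy.stats.rankdata(np.abs(d))
            w = ranks[d > 0].sum()
            n = len(d)
            mean, var = n * (n + 1) / 4, n * (n + 1) * (2 * n + 1) / 24
            approx = scipy.stats.norm.sf((w - mean - 0.5) / np.sqrt(var))
            assert abs(exact - approx) < 0.02

    def test_symmetric_data_two_sided_p_is_one(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        r = signed_rank_test(x, tail="two-sided")
        assert r.p_raw == 1.0

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            signed_rank_test(np.zeros(8))

    def test_zeros_dropped_from_n(self):
        r = signed_rank_test([0.0, 0.0, 1.0, 2.0, 3.0, -1.0, 2.5])
        assert r.n == 5

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30) + 0.5
        r = signed_rank_test(x, tail="greater")
        ref = scipy.stats.wilcoxon(x, alternative="greater",
                                   method="approx", correction=True).pvalue
        assert r.p_raw == pytest.approx(ref, abs=0.01)


class TestFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.037]), [0.037])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust(np.ones(5)), 1.0)

    def test_matches_step_up_formula_on_random_families(self, rng):
        """BH step-up oracle: p_(i)_adj = min_{j>=i}(p_(j) m / j), capped."""
        for _ in range(30):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            order = np.argsort(p)
            ps = p[order]
            adj_sorted = np.minimum.accumulate(
                (ps * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)

    def test_monotone_in_raw_order(self, rng):
        p = rng.random(25)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])
        with pytest.raises(ValueError, match="empty"):
            fdr_adjust([])

    def test_attach_fdr_sets_family(self):
        results = [StatResult(1.0, p, 10, "t", "two-sided")
                   for p in (0.01, 0.04)]
        attach_fdr(results, family="demo")
        assert all(r.family == "demo" for r in results)
        assert all(r.p_fdr >= r.p_raw for r in results)

    def test_fdr_control_under_mixed_nulls(self):
        """Rejecting at q = 0.1 controls the empirical FDR with 90% true
        nulls (modest replicate count; the heavy version runs elsewhere)."""
        rng = np.random.default_rng(7)
        q, fdps = 0.1, []
        for _ in range(400):
            p_null = rng.random(18)
            p_alt = rng.beta(0.1, 8.0, 2)
            p = np.concatenate([p_null, p_alt])
            rejected = fdr_adjust(p) <= q
            false = rejected[:18].sum()
            fdps.append(false / max(rejected.sum(), 1))
        assert np.mean(fdps) <= q + 0.02


def _table_to_df(table):
    s, a, b = table.shape
    rows = [
        {"subject": i, "A": j, "B": k, "y": table[i, j, k]}
        for i in range(s) for j in range(a) for k in range(b)
    ]
    return pd.DataFrame(rows)


class TestArtAnova:
    def test_alignment_hand_example(self):
        """2x2, 4 subjects, hand-computable cell-mean alignment."""
        # additive construction: subject effect + A effect, no B, no A:B
        table = np.zeros((4, 2, 2))
        subj = np.array([0.0, 1.0, 2.0, 3.0])
        a_eff = np.array([0.0, 10.0])
        for i in range(4):
            for j in range(2):
                for k in range(2):
                    table[i, j, k] = subj[i] + a_eff[j]
        ranks_b = align_rank(table, "B")
        # B-aligned responses strip subject and A effects entirely -> all
        # aligned values equal -> all midranks equal
        assert np.all(ranks_b == ranks_b.ravel()[0])
        ranks_a = align_rank(table, "A")
        # A-aligned: the 8 low-level values tie below the 8 high-level ones,
        # so the midranks are (1+...+8)/8 = 4.5 and (9+...+16)/8 = 12.5
        low, high = ranks_a[:, 0, :], ranks_a[:, 1, :]
        assert np.all(low == 4.5) and np.all(high == 12.5)

    def test_pure_main_effect_detected_and_others_null(self):
        rng = np.random.default_rng(1)
        table = (rng.standard_normal((12, 2, 3)) * 0.5
                 + np.array([0.0, 3.0])[None, :, None])
        res = art_rm_anova(_table_to_df(table), "y", "subject", ("A", "B"))
        assert res["A"].p_raw < 1e-4
        assert res["B"].p_raw > 0.01
        assert res["A:B"].p_raw > 0.01

    def test_invariance_under_positive_affine_transform(self):
        """Shifting and positively rescaling the responses commutes with the
        cell-mean alignment, so every aligned rank — and hence every ART
        statistic — is unchanged.  (General monotone transforms do change
        the cell means and are *not* expected to preserve ART statistics.)"""
        rng = np.random.default_rng(2)
        table = rng.standard_normal((8, 2, 2)) + 1.0
        df1 = _table_to_df(table)
        df2 = _table_to_df(3.7 * table - 11.0)
        r1 = art_rm_anova(df1, "y", "subject", ("A", "B"))
        r2 = art_rm_anova(df2, "y", "subject", ("A", "B"))
        for eff in r1:
            assert r1[eff].statistic == pytest.approx(r2[eff].statistic)

    def test_f_matches_statsmodels_anovarm_on_ranks(self):
        """The closed-form within-subject ANOVA agrees with statsmodels
        AnovaRM applied to the same aligned ranks."""
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(3)
        table = rng.standard_normal((10, 3, 2)) + rng.standard_normal((10, 1, 1))
        res = art_rm_anova(_table_to_df(table), "y", "subject", ("A", "B"))
        for eff, code in (("A", "A"), ("B", "B"), ("A:B", "A:B")):
            ranks = align_rank(table, code)
            df = _table_to_df(ranks)
            sm = AnovaRM(df, "y", "subject", within=["A", "B"]).fit()
            row = sm.anova_table.loc[eff.replace("A:B", "A:B")]
            assert res[eff].statistic == pytest.approx(row["F Value"],
                                                       rel=1e-8)
            assert res[eff].p_raw == pytest.approx(row["Pr > F"], rel=1e-6)

    def test_missing_cell_rejected(self):
        df = _table_to_df(np.zeros((3, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError, match="missing cell"):
            art_rm_anova(df, "y", "subject", ("A", "B"))

    def test_interaction_type_one_error_with_main_effects(self):
        """Interaction test keeps its size under a null that contains both
        main effects (small replicate version of the calibration run)."""
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            table = (rng.standard_normal((10, 2, 2))
                     + np.array([0.0, 1.5])[None, :, None]
                     + np.array([0.0, -1.0])[None, None, :])
            res = art_rm_anova(_table_to_df(table), "y", "subject", ("A", "B"))
            hits += res["A:B"].p_raw < 0.05
        assert abs(hits / n_rep - 0.05) < 0.025


class TestTTest:
    def test_hand_arithmetic(self):
        r = one_sample_ttest([1.0, 2.0, 3.0], mu=0.0)
        assert r.statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)))
        assert r.df == (2,)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_sample_ttest([2.0, 2.0, 2.0], mu=2.0)

    def test_tails_complementary(self, rng):
        x = rng.standard_normal(12)
        pg = one_sample_ttest(x, tail="greater").p_raw
        pl = one_sample_ttest(x, tail="less").p_raw
        assert pg + pl == pytest.approx(1.0, abs=1e-12)


class TestLinearTrend:
    def test_descending_values_slope_minus_one(self):
        slopes, _ = linear_trend_slope(np.array([[4.0, 3.0, 2.0, 1.0]] * 6))
        np.testing.assert_allclose(slopes, -1.0, atol=1e-12)

    def test_constant_values_no_trend(self):
        slopes, res = linear_trend_slope(np.full((6, 4), 2.0))
        np.testing.assert_allclose(slopes, 0.0, atol=1e-12)
        assert res.p_raw == 1.0

    def test_recovers_generative_slope(self, rng):
        s_true = -0.05
        levels = np.arange(4.0)
        values = 0.3 + s_true * levels + 0.01 * rng.standard_normal((30, 4))
        slopes, res = linear_trend_slope(values, tail="less")
        assert np.mean(slopes) == pytest.approx(s_true, abs=0.01)
        assert res.p_raw < 0.001

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="3 ordered levels"):
            linear_trend_slope(np.zeros((4, 2)))
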