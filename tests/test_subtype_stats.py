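import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import comb

from pdsubtype import (
    ancova_adjust,
    characterize,
    choose_test,
    compare_categorical,
    compare_continuous,
    fdr_correct,
    protein_screen,
)

from conftest import bh_stepup_oracle


def hand_anova(groups):
    """Textbook one-way ANOVA F and p from sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    F = (ssb / df1) / (ssw / df2)
    return F, sps.f.sf(F, df1, df2)


def fisher_2x2_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration over all tables
    with the observed margins, summing tables no more probable than the
    observed one."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    def prob(x):
        return (
            comb(r1, x, exact=True)
            * comb(r2, c1 - x, exact=True)
            / comb(n, c1, exact=True)
        )
    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestChooseTest:
    def test_equal_variance_gaussian_gives_anova(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(0.5, 1, 40), rng.normal(1, 1, 40)])
        groups = np.repeat(["a", "b", "c"], 40)
        assert choose_test(values, groups) == "anova"

    def test_unequal_variance_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            values = np.concatenate(
                [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(0, 10, 30)]
            )
            groups = np.repeat(["a", "b", "c"], 30)
            hits += choose_test(values, groups) == "anova_white"
        assert hits >= 38  # >= 95%

    def test_heavy_tails_go_nonparametric(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            values = np.concatenate([rng.standard_t(1, 50) for _ in range(3)])
            groups = np.repeat(["a", "b", "c"], 50)
            hits += choose_test(values, groups) == "kruskal_wallis"
        assert hits >= 11  # majority

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="b"):
            choose_test(np.arange(6.0), ["a", "a", "a", "a", "b", "b"])


class TestCompareContinuous:
    def test_two_group_anova_equals_pooled_t_test(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 1, 25)
        values = np.concatenate([x, y])
        groups = np.repeat(["a", "b"], 25)
        res = compare_continuous(values, groups, "anova")
        t_p = sps.ttest_ind(x, y, equal_var=True).pvalue
        assert res.p_nominal == pytest.approx(t_p, rel=1e-10)

    def test_fixed_fixture_matches_textbook_arithmetic(self):
        groups = [
            np.array([5.0, 7.0, 6.0, 8.0, 9.0]),
            np.array([11.0, 12.0, 10.0, 13.0, 14.0]),
            np.array([4.0, 3.0, 5.0, 4.0, 6.0]),
        ]
        values = np.concatenate(groups)
        labels = np.repeat(["g1", "g2", "g3"], 5)
        res = compare_continuous(values, labels, "anova")
        _, p = hand_anova(groups)
        assert res.p_nominal == pytest.approx(p, abs=1e-10)
        assert res.posthoc  # strongly separated means trigger post-hoc
        sig = {pair for pair, _, s in res.posthoc if s}
        assert (("g1", "g2")) in sig

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 20)
        values = np.concatenate([base, base, base])
        groups = np.repeat(["a", "b", "c"], 20)
        res = compare_continuous(values, groups, "anova")
        assert res.p_nominal > 0.99
        assert res.posthoc == []

    def test_white_branch_detects_shift_under_heteroscedasticity(self):
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.normal(0, 1, 40), rng.normal(0, 4, 40), rng.normal(3, 8, 40)]
        )
        groups = np.repeat(["a", "b", "c"], 40)
        res = compare_continuous(values, groups, "anova_white")
        assert res.test_used == "anova_white"
        assert 0 <= res.p_nominal <= 1

    def test_kruskal_branch_posthoc_uses_bh(self):
        rng = np.random.default_rng(6)
        values = np.concatenate(
            [rng.exponential(1, 30), rng.exponential(1, 30), rng.exponential(5, 30)]
        )
        groups = np.repeat(["a", "b", "c"], 30)
        res = compare_continuous(values, groups, "kruskal_wallis")
        if res.p_nominal < 0.05:
            raw = [
                sps.ranksums(values[groups == a], values[groups == b]).pvalue
                for a, b in [("a", "b"), ("a", "c"), ("b", "c")]
            ]
            expected = fdr_correct(raw)
            got = [p for _, p, _ in res.posthoc]
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compare_continuous(np.ones(9), np.repeat(["a", "b", "c"], 3), "anova")


class TestCompareCategorical:
    def test_2x2_matches_hypergeometric_enumeration(self):
        for table in ([[10, 0], [0, 10]], [[8, 2], [3, 7]], [[5, 5], [5, 5]]):
            res = compare_categorical(np.array(table))
            assert res.p_nominal == pytest.approx(fisher_2x2_oracle(table), rel=1e-9)

    def test_identical_rows_give_p_one(self):
        res = compare_categorical(np.array([[6, 4], [6, 4]]))
        assert res.p_nominal == pytest.approx(1.0)

    def test_monte_carlo_close_to_enumeration_on_3x2(self):
        table = np.array([[8, 1], [2, 6], [3, 3]])
        exact = compare_categorical(table).p_nominal
        mc = compare_categorical(table, enumeration_cap=0, n_mc=100_000, seed=0).p_nominal
        se = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(mc - exact) < 3 * se + 2e-5

    def test_posthoc_pairs_for_three_groups(self):
        table = np.array([[20, 0], [18, 2], [2, 18]])
        res = compare_categorical(table)
        assert res.p_nominal < 0.05
        sig = {pair for pair, _, s in res.posthoc if s}
        assert (0, 2) in sig and (1, 2) in sig

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            compare_categorical(np.array([[0, 5], [0, 3]]))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical(np.array([[1, -2], [3, 4]]))


class TestAncova:
    def test_independent_covariates_leave_p_unchanged(self):
        rng = np.random.default_rng(7)
        n = 100
        groups = np.repeat(["a", "b", "c"], n)
        values = np.concatenate(
            [rng.normal(0, 1, n), rng.normal(0.3, 1, n), rng.normal(0.6, 1, n)]
        )
        cov = rng.normal(size=(3 * n, 2))
        p_adj = ancova_adjust(values, groups, cov)
        p_raw = sps.f_oneway(values[:n], values[n : 2 * n], values[2 * n :]).pvalue
        assert p_adj == pytest.approx(p_raw, abs=0.02)

    def test_confounded_effect_vanishes_after_adjustment(self):
        rng = np.random.default_rng(8)
        n = 80
        groups = np.repeat(["a", "b"], n)
        confounder = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        values = confounder + rng.normal(0, 0.3, 2 * n)
        p_raw = sps.f_oneway(values[:n], values[n:]).pvalue
        p_adj = ancova_adjust(values, groups, confounder[:, None])
        assert p_raw < 1e-6
        assert p_adj > 0.05

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            ancova_adjust(np.arange(12.0), np.repeat(["a", "b"], 6), np.ones((12, 1)))


class TestFdrCorrect:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.03]), [0.03])

    def test_hand_stepup_example(self):
        np.testing.assert_allclose(
            fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)
    )
    def test_matches_stepup_oracle_and_dominates_input(self, ps):
        got = fdr_correct(ps)
        np.testing.assert_allclose(got, bh_stepup_oracle(np.array(ps)), atol=1e-12)
        assert np.all(got >= np.asarray(ps) - 1e-15)
        assert np.all(got <= 1.0)


class TestProteinScreen:
    def _groups(self, n=103):
        return np.repeat([1, 2, 3], [60, 20, 23])[:n]

    def test_sd_filter_boundary_strict_less_than(self):
        rng = np.random.default_rng(9)
        n = 103
        def with_sd(target):
            x = rng.normal(size=n)
            return (x - x.mean()) / x.std(ddof=1) * target + 1.0
        proteins = pd.DataFrame({"keep": with_sd(0.30), "drop": with_sd(0.29)})
        res = protein_screen(proteins, self._groups(), sd_min=0.3)
        assert res.n_after_sd_filter == 1
        assert set(res.all_tests["protein"]) == {"keep"}

    def test_missing_proteins_dropped_and_counts_nested(self):
        rng = np.random.default_rng(10)
        n = 103
        proteins = pd.DataFrame(rng.normal(1, 0.5, (n, 6)), columns=[f"p{i}" for i in range(6)])
        proteins.iloc[3, 0] = np.nan
        res = protein_screen(proteins, self._groups())
        assert res.n_input == 6
        assert res.n_after_missing_filter == 5
        assert res.n_input >= res.n_after_missing_filter >= res.n_after_sd_filter >= len(res.hits)

    def test_shifted_proteins_recovered(self):
        rng = np.random.default_rng(11)
        n = 103
        groups = self._groups()
        P = rng.normal(1.0, 0.4, (n, 60))
        P[groups == 3, :4] += 0.6  # 1.5 SD shift in the smallest subtype
        proteins = pd.DataFrame(P, columns=[f"p{i}" for i in range(60)])
        res = protein_screen(proteins, groups)
        assert set(res.hits["protein"]) >= {"p0", "p1", "p2", "p3"}
        assert all("3" in ph for ph in res.hits["posthoc"][:4])

    def test_empty_result_not_error(self):
        rng = np.random.default_rng(12)
        proteins = pd.DataFrame(rng.normal(0, 0.1, (103, 5)))
        res = protein_screen(proteins, self._groups())
        assert res.n_after_sd_filter == 0
        assert len(res.hits) == 0


class TestCharacterize:
    def test_panel_fdr_over_all_rows_and_report_shape(self):
        rng = np.random.default_rng(13)
        n = 103
        groups = np.repeat([1, 2, 3], [60, 20, 23])
        data = pd.DataFrame(
            {
                "severity": np.concatenate(
                    [rng.normal(5, 2, 60), rng.normal(9, 2, 20), rng.normal(13, 2, 23)]
                ),
                "age": rng.normal(67, 6, n),
                "pd_duration": rng.normal(6, 3, n),
                "sex": rng.choice(["male", "female"], n),
            },
            index=pd.Index(range(n), name="patient_id"),
        )
        table = characterize(
            data, groups,
            continuous=["severity", "age"],
            categorical=["sex"],
            ancova_variables=["severity"],
        )
        assert len(table.rows) == 3
        nominal = [r.p_nominal for r in table.rows]
        np.testing.assert_allclose(
            [r.p_fdr for r in table.rows], fdr_correct(nominal), atol=1e-12
        )
        severity = next(r for r in table.rows if r.variable == "severity")
        assert severity.p_nominal < 1e-6
        assert severity.ancova_p is not None
        frame = table.to_frame()
        assert {"test", "p", "p_fdr"} <= set(frame.columns)
        assert "subtype_1" in frame.columns
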