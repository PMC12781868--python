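"""Cross-sectional inference kernels against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortasym.inference import (
    adjusted_permutation_test,
    ancova_group_test,
    bh_adjust,
    demographics_table,
    fisher_exact_rxc,
    pairwise_permutation_report,
    roc_auc,
    roc_battery,
)


class TestBHAdjust:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.9]), [0.03, 0.06, 0.9])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_bounds_and_rank_monotonicity(self, rng):
        p = rng.uniform(0, 1, 30)
        adj = bh_adjust(p)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFisherExact:
    def test_hand_enumerated_2x2(self):
        assert fisher_exact_rxc([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-12)

    def test_matches_scipy_on_2x2(self, rng):
        for _ in range(25):
            t = rng.integers(0, 12, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            expected = stats.fisher_exact(t)[1]
            assert fisher_exact_rxc(t) == pytest.approx(expected, abs=1e-9)

    def test_rxc_enumeration_vs_monte_carlo(self):
        table = [[8, 3, 4], [2, 7, 6]]
        exact = fisher_exact_rxc(table)
        mc = fisher_exact_rxc(table, max_tables=1, n_monte_carlo=40000, seed=5)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_independence_gives_large_p(self):
        assert fisher_exact_rxc([[10, 10], [10, 10]]) == pytest.approx(1.0, abs=1e-9)


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert r.auc == 1.0

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [True, False, True, False]).auc == 0.5

    @pytest.mark.parametrize(
        "positives,expected",
        [((2, 3), 1.0),  # positives hold the two largest scores
         ((0, 3), 0.5),  # concordant pairs (4>2), (4>3); discordant (1<2), (1<3)
         ((1, 3), 0.75)],
    )
    def test_hand_counted_pairs(self, positives, expected):
        scores = [1, 2, 3, 4]
        is_pos = [i in positives for i in range(4)]
        assert roc_auc(scores, is_pos).auc == pytest.approx(expected)

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 25))
            score = rng.choice(np.arange(10) / 3.0, size=n)  # force ties
            is_pos = rng.random(n) < 0.5
            if is_pos.all() or not is_pos.any():
                continue
            pos, neg = score[is_pos], score[~is_pos]
            brute = np.mean([
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a, b in itertools.product(pos, neg)
            ])
            assert roc_auc(score, is_pos).auc == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    def test_hippocampal_volume_orientation(self, dian_small_table):
        base = dian_small_table[dian_small_table.visit == 0]
        res = {r.marker: r.auc for r in roc_battery(base, "SMC", "CTR")}
        # smaller hippocampus in disease must still yield AUC > 0.5 after negation
        assert res["hippocampal_volume"] > 0.5
        assert res["nfl_plasma"] > 0.5


class TestANCOVA:
    def test_identical_y_gives_null(self, rng):
        y = np.full(30, 0.4)
        group = np.repeat(["A", "B", "C"], 10)
        cov = pd.DataFrame({"age": rng.uniform(30, 60, 30)})
        res = ancova_group_test(y, group, cov)
        assert res["F"] == pytest.approx(0.0, abs=1e-20)
        assert res["p"] == pytest.approx(1.0)

    def test_no_covariates_equals_textbook_anova(self, rng):
        """F must equal the one-way ANOVA F from explicit sums of squares."""
        y = rng.normal(0, 1, 45) + np.repeat([0.0, 0.5, 1.0], 15)
        group = np.repeat(["A", "B", "C"], 15)
        res = ancova_group_test(y, group, None)
        grand = y.mean()
        ss_between = sum(15 * (y[group == g].mean() - grand) ** 2 for g in "ABC")
        ss_within = sum(((y[group == g] - y[group == g].mean()) ** 2).sum() for g in "ABC")
        f_oracle = (ss_between / 2) / (ss_within / 42)
        assert res["F"] == pytest.approx(f_oracle, abs=1e-9)
        assert res["p"] == pytest.approx(stats.f_oneway(*[y[group == g] for g in "ABC"]).pvalue)

    def test_collinear_covariate_named(self, rng):
        y = rng.normal(size=20)
        group = np.repeat(["A", "B"], 10)
        age = rng.uniform(30, 60, 20)
        cov = pd.DataFrame({"age": age, "age_copy": age})
        with pytest.raises(ValueError, match="age"):
            ancova_group_test(y, group, cov)

    def test_pairwise_contrasts_bh_family(self, rng):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 1, 20), rng.normal(2, 1, 20)])
        group = np.repeat(["A", "B", "C"], 20)
        res = ancova_group_test(y, group, None)
        df = res["pairwise"].to_frame()
        assert set(zip(df.group_a, df.group_b)) == {("A", "B"), ("A", "C"), ("B", "C")}
        np.testing.assert_allclose(df["p_adjusted"], bh_adjust(df["p_raw"].to_numpy()))


class TestPermutationTest:
    def test_constant_group_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            adjusted_permutation_test(rng.normal(size=10), ["A"] * 10, None, 99, 0)

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError, match="99"):
            adjusted_permutation_test(rng.normal(size=10), ["A", "B"] * 5, None, 50, 0)

    def test_separated_groups_exhaustive_p(self):
        """Perfect separation at n=6 (3+3): only the 2/20 extreme splits tie the F."""
        y = np.array([1.0, 1.1, 1.2, 9.0, 9.1, 9.2])
        group = ["A", "A", "A", "B", "B", "B"]
        res = adjusted_permutation_test(y, group, None, n_permutations=9999, seed=0)
        # enumeration oracle: F* >= F_obs exactly when the permutation recreates
        # the observed split or its mirror -> 2 * 3! * 3! / 6! = 0.1
        assert res.p_value == pytest.approx(0.1, abs=0.015)

    def test_affine_invariance_of_p(self, rng):
        y = rng.normal(size=40)
        group = rng.choice(["A", "B"], 40)
        cov = pd.DataFrame({"age": rng.uniform(30, 60, 40)})
        r1 = adjusted_permutation_test(y, group, cov, 999, seed=7)
        r2 = adjusted_permutation_test(3.5 * y - 2.0, group, cov, 999, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.statistic_observed == pytest.approx(r2.statistic_observed, rel=1e-9)

    def test_constant_covariate_tolerated(self, rng):
        y = rng.normal(size=20)
        group = np.repeat(["A", "B"], 10)
        cov = pd.DataFrame({"c": np.ones(20)})
        res = adjusted_permutation_test(y, group, cov, 199, seed=1)
        assert 0 < res.p_value <= 1

    def test_type_i_error_calibrated_under_null(self, rng):
        """y generated from the covariate-only model: rejections ~ alpha."""
        rejections = 0
        n_datasets = 120
        for i in range(n_datasets):
            n = 60
            age = rng.uniform(30, 70, n)
            eyo = rng.uniform(-20, 5, n)
            sex = rng.choice(["female", "male"], n)
            group = np.repeat(["CTR", "AMC", "SMC"], n // 3)
            y = 0.3 + 0.002 * age + 0.003 * eyo + 0.01 * (sex == "male") + rng.normal(0, 0.05, n)
            cov = pd.DataFrame({"age": age, "eyo": eyo, "sex": sex})
            res = adjusted_permutation_test(y, group, cov, n_permutations=499, seed=9000 + i)
            rejections += res.p_value < 0.05
        rate = rejections / n_datasets
        assert 0.01 <= rate <= 0.11  # wide band for 120 datasets; tight check in acceptance

    def test_agrees_with_ancova_under_true_effect(self, rng):
        """Zero covariate effects: permutation and ANCOVA should co-reject."""
        agree = 0
        n_rep = 40
        for i in range(n_rep):
            n = 60
            group = np.repeat(["CTR", "SMC"], n // 2)
            y = 0.3 + 0.06 * (group == "SMC") + rng.normal(0, 0.08, n)
            cov = pd.DataFrame({"age": rng.uniform(30, 70, n)})
            p_perm = adjusted_permutation_test(y, group, cov, 499, seed=100 + i).p_value
            p_anc = ancova_group_test(y, group, cov)["p"]
            agree += (p_perm < 0.05) == (p_anc < 0.05)
        assert agree / n_rep >= 0.9

    def test_pairwise_report_covers_all_pairs(self, barcelona_table):
        base = barcelona_table[barcelona_table.visit == 0].reset_index(drop=True)
        cov = base[["age_years", "sex", "eyo_years"]]
        rep = pairwise_permutation_report(base.cai, base.group, cov, 499, seed=2)
        df = rep.to_frame()
        assert len(df) == 3
        assert (df.p_adjusted <= 1).all() and (df.p_raw > 0).all()


class TestDemographics:
    def test_identical_values_flagged_missing(self, rng):
        df = pd.DataFrame({
            "group": np.repeat(["A", "B"], 10),
            "age_years": np.full(20, 50.0),
            "sex": ["female"] * 20,
        })
        with pytest.warns(UserWarning):
            out = demographics_table(df, continuous=("age_years",), discrete=("sex",))
        assert out.loc[out.variable == "age_years", "p"].isna().all()
        assert out.loc[out.variable == "sex", "p"].isna().all()

    def test_kruskal_null_identity(self):
        df = pd.DataFrame({
            "group": np.repeat(["A", "B"], 6),
            "age_years": np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 2),
        })
        out = demographics_table(df, continuous=("age_years",), discrete=())
        h = stats.kruskal(df.age_years[:6], df.age_years[6:])
        assert out.p.iloc[0] == pytest.approx(h.pvalue)

    def test_anova_null_p_uniform(self, rng):
        """Three groups from one Normal: the table's ANOVA p-values ~ Uniform(0,1)."""
        ps = []
        group = np.repeat(["A", "B", "C"], 10)
        for _ in range(300):
            df = pd.DataFrame({"group": group, "age_years": rng.normal(0, 1, 30)})
            out = demographics_table(df, continuous_test="anova",
                                     continuous=("age_years",), discrete=())
            ps.append(out.p.iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_group_summaries_formatted(self, dian_small_table):
        base = dian_small_table[dian_small_table.visit == 0]
        out = demographics_table(base, continuous_test="anova", seed=3)
        assert {"variable", "CTR", "AMC", "SMC", "test", "p"} <= set(out.columns)
        age_row = out[out.variable == "age_years"].iloc[0]
        assert "(" in age_row["CTR"]  # "mean (SD)" formatting
        assert age_row.p < 0.001  # age differs strongly by design
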