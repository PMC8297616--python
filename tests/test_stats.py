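"""Statistical toolkit: ANOVA, t-tests, effect sizes, correlation, HWE."""

import itertools

import numpy as np
import pandas as pd
import pytest

from twostep import (
    GenotypeCounts,
    InvalidInputError,
    hwe_exact_test,
    independent_t,
    independent_t_from_summary,
    mixed_anova,
    paired_t,
    partial_eta_sq,
    pearson_r,
    standardized_diff_from_t,
)
from twostep.stats import hwe_het_distribution


class TestPartialEtaSq:
    def test_identity_values(self):
        assert partial_eta_sq(39.63, 1, 39) == pytest.approx(0.504, abs=5e-4)
        assert partial_eta_sq(0.0, 1, 39) == 0.0

    def test_monotone_in_f(self):
        vals = [partial_eta_sq(f, 1, 39) for f in (0.5, 2, 8, 32)]
        assert vals == sorted(vals)
        assert all(0 <= v <= 1 for v in vals)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            partial_eta_sq(-1.0, 1, 39)
        with pytest.raises(InvalidInputError):
            partial_eta_sq(1.0, 0, 39)


class TestPairedT:
    def test_hand_computed_example(self):
        # differences (1,2,3,4): mean 2.5, SD 1.2910 -> t = 3.873, df = 3
        res = paired_t([2, 4, 6, 8], [1, 2, 3, 4])
        assert res.t == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2))
        assert res.t == pytest.approx(3.873, abs=1e-3)
        assert res.df == 3
        assert res.effect_size == pytest.approx(2.5 / 1.29099, abs=1e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = paired_t(x, y)
        from scipy import stats as sps

        ref = sps.ttest_rel(x, y)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert paired_t(x, y).t == pytest.approx(-paired_t(y, x).t)

    def test_identical_samples_flagged_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.t == 0.0 and res.p == 1.0

    def test_one_tailed_halves_two_tailed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 1, 20)
        y = rng.normal(0.0, 1, 20)
        two = paired_t(x, y)
        one = paired_t(x, y, tail="greater")
        if two.t > 0:
            assert one.p == pytest.approx(two.p / 2)


class TestIndependentT:
    def test_reconstructs_printed_group_comparison(self):
        # drift-phase delta stay frequencies: 9.2±4.5 (n=12) vs -3.1±2.8 (n=29)
        res = independent_t_from_summary(9.2, 4.5, 12, -3.1, 2.8, 29)
        assert res.df == 39
        assert round(res.t, 2) == 2.35
        # stable phase: 7.27±3.35 vs -3.8±2.19 -> printed 2.74 (input rounding)
        res2 = independent_t_from_summary(7.27, 3.35, 12, -3.8, 2.19, 29)
        assert res2.t == pytest.approx(2.74, abs=0.01)

    def test_equal_means_give_zero(self):
        res = independent_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 15)
        assert res.t == 0.0

    def test_summary_form_agrees_with_raw_data(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1, 2, 12), rng.normal(0, 2, 29)
        raw = independent_t(x, y)
        summ = independent_t_from_summary(
            x.mean(), x.std(ddof=1) / np.sqrt(12), 12,
            y.mean(), y.std(ddof=1) / np.sqrt(29), 29,
        )
        assert raw.t == pytest.approx(summ.t, abs=1e-10)
        assert raw.p == pytest.approx(summ.p, abs=1e-10)

    def test_pooled_df(self):
        assert independent_t_from_summary(1, 1, 12, 0, 1, 29).df == 39

    def test_invalid_sizes(self):
        with pytest.raises(InvalidInputError):
            independent_t_from_summary(1, 1, 1, 0, 1, 29)


class TestStandardizedDiff:
    @pytest.mark.parametrize(
        "t,expected", [(2.74, 0.94), (2.88, 0.99), (2.35, 0.81), (0.0, 0.0)]
    )
    def test_uncorrected_values(self, t, expected):
        assert round(standardized_diff_from_t(t, 12, 29), 2) == expected

    def test_correction_shrinks_magnitude(self):
        d = standardized_diff_from_t(2.74, 12, 29)
        g = standardized_diff_from_t(2.74, 12, 29, corrected=True)
        assert abs(g) < abs(d)
        assert g == pytest.approx(d * (1 - 3 / (4 * 39 - 1)))


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=41), rng.normal(size=41)
        res = pearson_r(x, y)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert res.r == pytest.approx(num / den, abs=1e-12)
        from scipy import stats as sps

        ref = sps.pearsonr(x, y)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
        assert res.n == 41

    def test_zero_variance_flagged(self):
        res = pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate


class TestHardyWeinberg:
    def test_study_counts_under_both_conventions(self):
        counts = GenotypeCounts(4, 25, 12)
        assert hwe_exact_test(counts) == pytest.approx(0.1179, abs=1e-3)
        assert hwe_exact_test(counts, method="doubled_tail") == pytest.approx(
            0.1849, abs=1e-3
        )

    def test_perfect_proportions_are_modal(self):
        # (25, 50, 25) sits at the mode: every table is "as probable or less"
        assert hwe_exact_test(GenotypeCounts(25, 50, 25)) == pytest.approx(1.0)

    def test_small_table_matches_brute_force_enumeration(self):
        # 4 individuals, 4 minor alleles: heterozygote count in {0, 2, 4}
        from math import comb, factorial

        def table_prob(h, n=4, minor=4):
            nm = (minor - h) // 2
            nM = n - h - nm
            num = factorial(n) / (factorial(nm) * factorial(h) * factorial(nM)) * 2**h
            return num / comb(2 * n, minor)

        dist = hwe_het_distribution(GenotypeCounts(1, 2, 1))
        for h, p in dist.items():
            assert p == pytest.approx(table_prob(h), rel=1e-12)
        p_obs = dist[2]
        expected = sum(p for p in dist.values() if p <= p_obs + 1e-12)
        assert hwe_exact_test(GenotypeCounts(1, 2, 1)) == pytest.approx(expected)

    def test_distribution_sums_to_one(self):
        for counts in [(4, 25, 12), (1, 2, 1), (0, 5, 40), (10, 0, 10)]:
            dist = hwe_het_distribution(GenotypeCounts(*counts))
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            GenotypeCounts(-1, 5, 5)


def _factorial_dataset(n_g1, n_g2, seed, effects=None):
    """Long-format 2x2x2 within x 2 between dataset with known structure."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for i in range(n_g1 + n_g2):
        g = "G1" if i < n_g1 else "G2"
        subj_eff = rng.normal(0, 1)
        for r_ in ("rew", "non"):
            for t_ in ("com", "rar"):
                for c_ in ("ear", "lat"):
                    mu = subj_eff
                    mu += effects.get("R", 0) * (1 if r_ == "rew" else -1)
                    mu += effects.get("G", 0) * (1 if g == "G1" else -1)
                    rows.append(
                        {
                            "subj": f"s{i}",
                            "grp": g,
                            "R": r_,
                            "T": t_,
                            "C": c_,
                            "y": mu + rng.normal(),
                        }
                    )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_type3_glm_oracle_on_unbalanced_design(self):
        """Every F equals a projection-based Type III GLM on contrast scores."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = _factorial_dataset(4, 5, seed=7, effects={"R": 0.5, "G": 0.7})
        mine = mixed_anova(df, dv="y", subject="subj", within=["R", "T", "C"], between="grp")
        assert len(mine) == 15

        wide = df.pivot_table(index="subj", columns=["R", "T", "C"], values="y")
        grp = df.groupby("subj")["grp"].first().loc[wide.index]
        levels = {"R": ["rew", "non"], "T": ["com", "rar"], "C": ["ear", "lat"]}
        cols = list(wide.columns)
        codes = {
            f: np.array([1.0 if col[i] == levels[f][0] else -1.0 for col in cols])
            for i, f in enumerate(["R", "T", "C"])
        }
        oracle = {}
        for k in range(1, 4):
            for combo in itertools.combinations(["R", "T", "C"], k):
                c = np.ones(len(cols))
                for f in combo:
                    c = c * codes[f]
                y = wide.to_numpy() @ (c / len(cols))
                d = pd.DataFrame({"y": y, "grp": grp.to_numpy()})
                a = sm.stats.anova_lm(smf.ols("y ~ C(grp, Sum)", data=d).fit(), typ=3)
                oracle[" × ".join(combo)] = (
                    a.loc["Intercept", "F"],
                    a.loc["C(grp, Sum)", "F"],
                )
        d = pd.DataFrame({"y": wide.to_numpy().mean(axis=1), "grp": grp.to_numpy()})
        a = sm.stats.anova_lm(smf.ols("y ~ C(grp, Sum)", data=d).fit(), typ=3)
        oracle["grp"] = (None, a.loc["C(grp, Sum)", "F"])

        for _, row in mine.iterrows():
            eff = row["effect"]
            if eff == "grp":
                f_ref = oracle["grp"][1]
            elif eff.endswith(" × grp"):
                f_ref = oracle[eff[: -len(" × grp")]][1]
            else:
                f_ref = oracle[eff][0]
            assert row["F"] == pytest.approx(f_ref, abs=1e-8)

    def test_matches_pingouin_on_balanced_design(self):
        import pingouin as pg

        df = _factorial_dataset(6, 6, seed=8, effects={"R": 0.4})
        sub = df[(df["T"] == "com") & (df["C"] == "ear")]
        mine = mixed_anova(sub, dv="y", subject="subj", within=["R"], between="grp")
        ref = pg.mixed_anova(
            data=sub, dv="y", within="R", subject="subj", between="grp"
        ).set_index("Source")
        lookup = {"R": "R", "grp": "grp", "R × grp": "Interaction"}
        for _, row in mine.iterrows():
            assert row["F"] == pytest.approx(ref.loc[lookup[row["effect"]], "F"], rel=1e-9)
            assert row["p"] == pytest.approx(ref.loc[lookup[row["effect"]], "p_unc"], rel=1e-9)

    def test_effect_rows_in_table_order(self):
        df = _factorial_dataset(3, 4, seed=9)
        mine = mixed_anova(df, dv="y", subject="subj", within=["R", "T", "C"], between="grp")
        assert list(mine["effect"][:5]) == ["R", "T", "C", "grp", "R × T"]
        assert mine["effect"].iloc[-1] == "R × T × C × grp"
        assert (mine["df1"] == 1).all()
        assert (mine["df2"] == 5).all()  # n - 2 groups

    def test_partial_eta_identity_against_sums_of_squares(self):
        df = _factorial_dataset(5, 7, seed=10, effects={"R": 0.6, "G": 0.4})
        mine = mixed_anova(df, dv="y", subject="subj", within=["R", "T", "C"], between="grp")
        for _, row in mine.iterrows():
            assert row["partial_eta_sq"] == pytest.approx(
                row["ss_effect"] / (row["ss_effect"] + row["ss_error"]), rel=1e-10
            )
            assert row["partial_eta_sq"] == pytest.approx(
                partial_eta_sq(row["F"], row["df1"], row["df2"]), rel=1e-10
            )

    def test_constant_responses_give_zero_f(self):
        df = _factorial_dataset(3, 3, seed=11)
        df["y"] = 5.0
        mine = mixed_anova(df, dv="y", subject="subj", within=["R", "T", "C"], between="grp")
        assert (mine["F"] == 0.0).all()
        assert (mine["p"] == 1.0).all()

    def test_missing_cell_names_subject(self):
        df = _factorial_dataset(3, 3, seed=12)
        df = df.drop(df[(df["subj"] == "s2") & (df["R"] == "rew") & (df["T"] == "com") & (df["C"] == "ear")].index)
        with pytest.raises(InvalidInputError, match="s2"):
            mixed_anova(df, dv="y", subject="subj", within=["R", "T", "C"], between="grp")

    def test_tiny_group_rejected(self):
        df = _factorial_dataset(1, 5, seed=13)
        sub = df[(df["T"] == "com") & (df["C"] == "ear")]
        with pytest.raises(InvalidInputError, match="fewer than 2"):
            mixed_anova(sub, dv="y", subject="subj", within=["R"], between="grp")
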