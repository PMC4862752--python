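import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

import szquant as sz

from oracles import ancova_oracle, mixed_anova_oracle


def make_mixed_table(seed=0, n=8, group_shift=0.0, interaction=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, gname in enumerate(("vehicle", "drug")):
        for s in range(n):
            subj_eff = rng.normal(0, 1.0)
            for t, tname in enumerate(("hour1", "hour2")):
                y = rng.normal(0, 1.0) + subj_eff + g * group_shift + g * t * interaction
                rows.append(dict(subject=f"{gname}{s}", group=gname, time=tname, response=y))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_groups_null_interaction(self):
        df = make_mixed_table(seed=1)
        half = df[df.group == "vehicle"].copy()
        mirrored = half.copy()
        mirrored["group"] = "drug"
        mirrored["subject"] = mirrored["subject"].str.replace("vehicle", "drug")
        res = sz.mixed_anova(pd.concat([half, mirrored]))
        assert res["interaction"]["F"] == pytest.approx(0.0, abs=1e-10)
        assert res["group"]["F"] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sums_of_squares_oracle(self, seed):
        df = make_mixed_table(seed=seed, group_shift=0.5, interaction=1.0)
        res = sz.mixed_anova(df)
        oracle = mixed_anova_oracle(df.response, df.group, df.time, df.subject)
        for eff in ("group", "time", "interaction"):
            assert res[eff]["F"] == pytest.approx(oracle[eff], abs=1e-8)
        assert (res["interaction"]["df1"], res["interaction"]["df2"]) == oracle["df"]["interaction"]

    def test_detects_true_interaction(self):
        """Power check at a strong, known interaction: rejection in most
        replicates (scaled-down simulation)."""
        hits = sum(
            sz.mixed_anova(make_mixed_table(seed=s, interaction=2.0))["interaction"]["p"] < 0.05
            for s in range(20)
        )
        assert hits >= 16

    def test_incomplete_within_rejected(self):
        df = make_mixed_table().iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            sz.mixed_anova(df)


class TestAncova:
    def _table(self, seed=0, n=10, confounded=False):
        rng = np.random.default_rng(seed)
        rows = []
        for gname in ("vehicle", "drug"):
            for s in range(n):
                dose = rng.uniform(7.5, 10.0) + (2.0 if confounded and gname == "drug" else 0.0)
                y = 0.5 * dose + (1.0 if gname == "drug" else 0.0) + rng.normal()
                rows.append(dict(subject=f"{gname}{s}", group=gname, dose=dose, response=y))
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_nested_ols_oracle(self, seed):
        df = self._table(seed=seed)
        res = sz.ancova(df)
        f, (df1, df2) = ancova_oracle(df.response, df.group, df.dose)
        assert res["group"]["F"] == pytest.approx(f, abs=1e-8)
        assert (res["group"]["df1"], res["group"]["df2"]) == (df1, df2)

    def test_adjustment_moves_f_in_predicted_direction(self):
        """When the drug group also got higher doses and dose raises the
        response, adjusting for dose shrinks the apparent drug effect."""
        df = self._table(seed=3, confounded=True)
        adjusted = sz.ancova(df)["group"]["F"]
        groups = [g.response.to_numpy() for _, g in df.groupby("group")]
        unadjusted = sst.f_oneway(*groups).statistic
        assert adjusted < unadjusted

    def test_constant_covariate_rejected(self):
        df = self._table()
        df["dose"] = 10.0
        with pytest.raises(ValueError, match="covariate"):
            sz.ancova(df)

    def test_collinear_covariate_rejected(self):
        df = self._table()
        df["dose"] = np.where(df.group == "drug", 10.0, 7.5)
        with pytest.raises(ValueError, match="collinear"):
            sz.ancova(df)


class TestPosthocAndChi2:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(1.2, 1, 12)
        res = sz.posthoc_ttests([(a, b), (a, a + 0.01)])
        for r in res:
            assert r["p_adj"] == pytest.approx(min(1.0, 2 * r["p_raw"]))

    def test_identical_samples_capped_at_one(self):
        a = np.arange(10.0)
        res = sz.posthoc_ttests([(a, a)] * 3)
        assert all(r["p_adj"] == 1.0 for r in res)

    def test_matches_scipy_t_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 2, 14)
        pooled = sz.posthoc_ttests([(a, b)], equal_var=True)[0]
        welch = sz.posthoc_ttests([(a, b)], equal_var=False)[0]
        sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2))
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(1 / a.size + 1 / b.size))
        assert pooled["t"] == pytest.approx(t_hand, abs=1e-12)
        assert pooled["t"] != pytest.approx(welch["t"], abs=1e-6)

    def test_chi_square_equal_proportions(self):
        out = sz.chi_square([[5, 5], [5, 5]])
        assert out["chi2"] == 0.0

    def test_chi_square_closed_form(self):
        table = np.array([[6, 0], [1, 4]])
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        out = sz.chi_square(table)
        assert out["chi2"] == pytest.approx(chi2_hand, abs=1e-12)
        assert out["df"] == 1

    def test_chi_square_row_swap_invariance(self):
        t = [[6, 2], [3, 7]]
        assert sz.chi_square(t)["chi2"] == pytest.approx(sz.chi_square(t[::-1])["chi2"])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            sz.chi_square([[0, 0], [3, 4]])


class TestCohensD:
    def test_identical_groups(self):
        a = np.arange(10.0)
        assert sz.cohens_d(a, a) == 0.0

    def test_unit_separation(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 4000)
        base = (base - base.mean()) / base.std(ddof=1)
        assert sz.cohens_d(base + 1.0, base) == pytest.approx(1.0, abs=1e-9)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(1, 2, 15), rng.normal(0, 1.5, 11)
        sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2))
        assert sz.cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / sp, abs=1e-12)


class TestNewmanKeuls:
    def test_equal_means_no_rejections(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 10)
        groups = [base + rng.normal(0, 1e-6, 10) for _ in range(4)]
        out = sz.newman_keuls(groups)
        assert not any(r["reject"] for r in out)

    def test_huge_separation_all_rejected(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(mu, 0.01, 8) for mu in (0.0, 10.0, 20.0)]
        out = sz.newman_keuls(groups)
        assert all(r["reject"] for r in out)

    def test_four_group_example_matches_manual_ladder(self):
        """Manual SNK on a 4-group layout: each q compared to the
        studentized-range quantile for its span, with the stepwise blocking
        rule applied by hand."""
        rng = np.random.default_rng(6)
        n = 10
        groups = [rng.normal(mu, 1.0, n) for mu in (0.0, 0.2, 2.5, 2.6)]
        out = {(r["group_low"], r["group_high"]): r for r in sz.newman_keuls(groups, labels="ABCD")}
        means = [g.mean() for g in groups]
        mse = np.mean([g.var(ddof=1) for g in groups])
        se = np.sqrt(mse / n)
        df_err = 4 * (n - 1)

        def q_manual(i, j):
            return abs(means[j] - means[i]) / se

        crit = {p: sst.studentized_range.ppf(0.95, p, df_err) for p in (2, 3, 4)}
        # widest pair spans 4 means
        assert out[("A", "D")]["reject"] == (q_manual(0, 3) > crit[4])
        # A-B and C-D are adjacent pairs (span 2)
        assert out[("A", "B")]["span"] == 2
        assert out[("A", "B")]["reject"] == (
            q_manual(0, 1) > crit[2] and q_manual(0, 3) > crit[4] and q_manual(0, 2) > crit[3]
        )
        assert out[("C", "D")]["reject"] == (q_manual(2, 3) > crit[2] and out[("A", "D")]["reject"] and out[("B", "D")]["reject"])

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            sz.newman_keuls([np.arange(5.0), np.arange(5.0)])
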