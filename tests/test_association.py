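"""Association screens against independent statistical oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gutlink.association import (
    ConstantInputError,
    adjusted_regression,
    association_screen,
    bh_adjust,
    differential_metabolites,
    exact_mwu_p,
    mannwhitney_diff,
    plsda_vip,
    spearman_screen,
)


def _covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.uniform(3, 12, n),
            "sex": rng.integers(0, 2, n),
            "group": ["case"] * (n // 2) + ["control"] * (n - n // 2),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestAdjustedRegression:
    def test_exact_fit_recovers_slope(self, rng):
        n = 30
        cov = _covariates(rng, n)
        g = rng.binomial(2, 0.4, n).astype(float)
        res = adjusted_regression(g, 2.0 * g, cov)
        assert res.beta == pytest.approx(2.0, abs=1e-10)
        assert res.p < 1e-15

    def test_matches_normal_equations_oracle(self, rng):
        # independent oracle: closed-form (X'X)^-1 X'y plus t distribution
        for _ in range(20):
            n = int(rng.integers(8, 30))
            cov = _covariates(rng, n)
            g = rng.binomial(2, 0.4, n).astype(float)
            while np.ptp(g) == 0:
                g = rng.binomial(2, 0.4, n).astype(float)
            y = rng.normal(size=n)
            X = np.column_stack([np.ones(n), g, cov["age"], cov["sex"]])
            bhat = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ bhat
            sigma2 = resid @ resid / (n - 4)
            se = math.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            p = 2 * stats.t.sf(abs(bhat[1] / se), n - 4)
            res = adjusted_regression(g, y, cov)
            assert res.beta == pytest.approx(bhat[1], abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 40
        cov = _covariates(rng, n)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.5 * g + rng.normal(size=n)
        X = sm.add_constant(np.column_stack([g, cov["age"], cov["sex"]]))
        fit = sm.OLS(y, X).fit()
        res = adjusted_regression(g, y, cov)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_covariate_equivariance(self, rng):
        # adding c*age to the feature must not move the genotype p-value
        n = 50
        cov = _covariates(rng, n)
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.normal(size=n)
        base = adjusted_regression(g, y, cov)
        shifted = adjusted_regression(g, y + 3.7 * cov["age"].to_numpy(), cov)
        assert shifted.beta == pytest.approx(base.beta, abs=1e-10)
        assert shifted.p == pytest.approx(base.p, abs=1e-10)

    def test_constant_genotype_skipped_with_reason(self, rng):
        cov = _covariates(rng, 20)
        with pytest.raises(ConstantInputError):
            adjusted_regression(np.ones(20), rng.normal(size=20), cov)

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(7)
        cov = _covariates(rng, 40)
        ps = []
        for _ in range(500):
            g = rng.binomial(2, 0.3, 40).astype(float)
            while np.ptp(g) == 0:
                g = rng.binomial(2, 0.3, 40).astype(float)
            ps.append(adjusted_regression(g, rng.normal(size=40), cov).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_screen_applies_bh_within_family(self, default_cohort):
        scr = association_screen(
            default_cohort.genotypes.iloc[:, :10],
            default_cohort.species.iloc[:, :5],
            default_cohort.covariates,
            transform="log10_offset",
        )
        assert len(scr) == 50
        np.testing.assert_allclose(scr["q"], bh_adjust(scr["p"].to_numpy()), atol=0)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.05, 0.5), (0.015, 0.075, 0.5)),
            ((0.2,), (0.2,)),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        np.testing.assert_allclose(bh_adjust(np.array(p)), expected, atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.5]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_matches_statsmodels_fdr_bh(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        q_theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), q_theirs, atol=1e-12)


def brute_force_bh(p):
    """Step-up definition applied literally: q_(i) = min_{j>=i} m p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q


class TestSpearmanScreen:
    def test_rank_invariance_and_antitone(self, rng):
        n = 12
        x = rng.normal(size=n)
        a = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(n)])
        b = pd.DataFrame(
            {"mono": np.exp(3 * x), "anti": -(x**3)}, index=a.index
        )
        out = spearman_screen(a, b).set_index("feature_b")
        assert out.loc["mono", "rho"] == pytest.approx(1.0)
        assert out.loc["anti", "rho"] == pytest.approx(-1.0)

    def test_constant_feature_flagged_undefined(self, rng):
        idx = [f"s{i}" for i in range(8)]
        a = pd.DataFrame({"x": rng.normal(size=8)}, index=idx)
        b = pd.DataFrame({"flat": np.ones(8)}, index=idx)
        out = spearman_screen(a, b)
        assert out.loc[0, "significance"] == "undefined"
        assert np.isnan(out.loc[0, "rho"])

    def test_too_few_shared_samples_rejected(self, rng):
        a = pd.DataFrame({"x": [1.0, 2, 3]}, index=["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            spearman_screen(a, a)


def enumerate_mwu_p(x, y):
    """Oracle: full enumeration of group assignments over pooled ranks."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    total = count_le = count_ge = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - offset
        total += 1
        count_le += u <= u_obs + 1e-9
        count_ge += u >= u_obs - 1e-9
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


class TestMannWhitney:
    def test_two_vs_two_enumeration_example(self):
        u, p = exact_mwu_p(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-15)

    def test_identical_groups_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        _, p = exact_mwu_p(x, x.copy())
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 3), (6, 6)])
    def test_exact_branch_matches_enumeration(self, n1, n2, rng):
        for _ in range(10):
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            _, p = exact_mwu_p(x, y)
            assert p == enumerate_mwu_p(x, y)

    def test_exact_branch_matches_enumeration_with_ties(self, rng):
        x = np.array([1.0, 2.0, 2.0, 5.0])
        y = np.array([2.0, 3.0, 3.0])
        _, p = exact_mwu_p(x, y)
        assert p == enumerate_mwu_p(x, y)

    def test_monotone_transform_leaves_u_unchanged(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=5)
        u1, p1 = exact_mwu_p(x, y)
        u2, p2 = exact_mwu_p(np.exp(x), np.exp(y))
        assert u1 == u2 and p1 == p2

    def test_differential_cytokine_table(self, default_cohort):
        out = mannwhitney_diff(default_cohort.cytokines, default_cohort.covariates)
        truth = {f for _, f, _ in default_cohort.truth.differential_features}
        called = set(out.loc[out["significant"], "feature_id"])
        assert called <= set(default_cohort.cytokines.columns)
        assert len(called & truth) >= 4  # embedded 1-log-unit shifts are found

    def test_nonpositive_values_instruct_offset(self, default_cohort):
        cyt = default_cohort.cytokines.copy()
        cyt.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="offset"):
            mannwhitney_diff(cyt, default_cohort.covariates)

    def test_large_groups_use_corrected_normal_approximation(self, rng):
        idx = [f"s{i}" for i in range(30)]
        table = pd.DataFrame({"c1": np.exp(rng.normal(size=30))}, index=idx)
        groups = pd.Series(["case"] * 15 + ["control"] * 15, index=idx)
        out = mannwhitney_diff(table, groups)
        expected = stats.mannwhitneyu(
            np.log(table["c1"][:15]), np.log(table["c1"][15:]),
            alternative="two-sided", method="asymptotic", use_continuity=True,
        ).pvalue
        assert out.loc[0, "p"] == pytest.approx(expected, abs=1e-12)


class TestVip:
    def test_single_feature_vip_is_one(self, rng):
        idx = [f"s{i}" for i in range(20)]
        table = pd.DataFrame({"m1": rng.normal(size=20)}, index=idx)
        groups = np.array([1] * 10 + [0] * 10)
        vip = plsda_vip(table, groups)
        assert vip["m1"] == pytest.approx(1.0, abs=1e-12)

    def test_sum_of_squares_identity(self, rng):
        for _ in range(10):
            n, p = int(rng.integers(10, 40)), int(rng.integers(2, 15))
            table = pd.DataFrame(
                rng.normal(size=(n, p)), index=[f"s{i}" for i in range(n)]
            )
            groups = rng.integers(0, 2, n)
            while groups.sum() < 2 or (1 - groups).sum() < 2:
                groups = rng.integers(0, 2, n)
            vip = plsda_vip(table, groups)
            assert (vip**2).sum() == pytest.approx(p, abs=1e-6)

    def test_informative_feature_attains_max_vip(self):
        rng = np.random.default_rng(1)
        n = 200
        groups = np.array([1] * 100 + [0] * 100)
        X = rng.normal(size=(n, 10))
        X[:, 3] += 2.0 * groups
        table = pd.DataFrame(X, columns=[f"m{j}" for j in range(10)],
                             index=[f"s{i}" for i in range(n)])
        vip = plsda_vip(table, groups)
        assert vip.idxmax() == "m3" and vip["m3"] > 1.0

    def test_matches_sklearn_pls_weights(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(3)
        n, p = 60, 8
        groups = rng.integers(0, 2, n)
        X = rng.normal(size=(n, p))
        X[:, 0] += groups
        table = pd.DataFrame(X, index=[f"s{i}" for i in range(n)])
        pls = PLSRegression(n_components=2, scale=True).fit(X, groups.astype(float))
        W = pls.x_weights_
        T = pls.x_scores_
        q = pls.y_loadings_.ravel()
        ssy = q**2 * np.einsum("ij,ij->j", T, T)
        vip_sklearn = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(plsda_vip(table, groups), vip_sklearn, atol=1e-8)


class TestDifferentialMetabolites:
    def _table(self, rng, tweak=None):
        n = 40
        idx = [f"s{i}" for i in range(n)]
        groups = pd.Series(["case"] * 20 + ["control"] * 20, index=idx)
        X = np.exp(rng.normal(5, 0.2, size=(n, 6)))
        if tweak:
            tweak(X)
        return pd.DataFrame(X, columns=[f"m{j}" for j in range(6)], index=idx), groups

    def test_up_shifted_metabolite_called(self, rng):
        table, groups = self._table(rng, lambda X: np.multiply(X[:20, 0], 3.0, out=X[:20, 0]))
        out = differential_metabolites(table, groups).set_index("feature_id")
        assert bool(out.loc["m0", "significant"])
        assert out.loc["m0", "fold_change"] > 1.5

    def test_down_shifted_metabolite_called_under_two_sided_fc(self, rng):
        table, groups = self._table(rng, lambda X: np.multiply(X[:20, 1], 1 / 3.0, out=X[:20, 1]))
        out = differential_metabolites(table, groups).set_index("feature_id")
        assert bool(out.loc["m1", "significant"])
        out1 = differential_metabolites(table, groups, two_sided_fc=False).set_index("feature_id")
        assert not bool(out1.loc["m1", "significant"])  # literal one-sided reading

    def test_all_three_cuts_required(self, rng):
        # a strong fold change with VIP forced low by a dominating feature
        def tweak(X):
            X[:20, 0] *= 50.0  # dominates the group axis -> takes the VIP mass
            X[:20, 1] *= 2.0
        table, groups = self._table(rng, tweak)
        out = differential_metabolites(table, groups).set_index("feature_id")
        row = out.loc["m1"]
        if row["vip"] <= 1.0:
            assert not row["significant"]
        sig = out[out["significant"]]
        assert ((sig["vip"] > 1) & (sig["p"] < 0.05)).all()
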