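import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decispeed import cohort_stats as cs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


class TestHierarchicalRegression:
    def test_orthogonal_r2_changes_sum(self, rng):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 2 * x1 + x2 + rng.normal(0, 0.5, n)
        table = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        steps = cs.hierarchical_regression(table, "y", [("a", ["x1"]), ("b", ["x2"])])
        total = steps[-1].r2
        assert steps[0].r2_change + steps[1].r2_change == pytest.approx(total, abs=1e-10)

    def test_duplicate_predictor_zero_change(self, rng):
        n = 40
        x = rng.normal(size=n)
        y = x + rng.normal(0, 0.5, n)
        table = pd.DataFrame({"y": y, "x": x})
        steps = cs.hierarchical_regression(table, "y", [("a", ["x"]), ("b", ["x"])])
        assert steps[1].r2_change == pytest.approx(0.0, abs=1e-12)
        assert steps[1].f_change == 0.0
        assert steps[1].p_change == 1.0

    def test_recovery_and_f_change_oracle(self, rng):
        n = 100
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 2 * x1 + x2 + rng.normal(size=n)
        table = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        steps = cs.hierarchical_regression(table, "y", [("a", ["x1"]), ("b", ["x2"])])
        # standardized betas near truth (scaled by sd ratios)
        bstd = steps[1].terms.loc["x1", "beta_std"]
        expected = 2 * x1.std(ddof=1) / y.std(ddof=1)
        assert bstd == pytest.approx(expected, abs=0.1)
        # independent nested-model F computation
        ssr1 = np.sum(
            (y - np.polyval(np.polyfit(x1, y, 1), x1)) ** 2
        )
        X2 = np.column_stack([np.ones(n), x1, x2])
        beta = np.linalg.lstsq(X2, y, rcond=None)[0]
        ssr2 = np.sum((y - X2 @ beta) ** 2)
        f_oracle = (ssr1 - ssr2) / 1 / (ssr2 / (n - 3))
        assert steps[1].f_change == pytest.approx(f_oracle, rel=1e-9)
        p_oracle = stats.f.sf(f_oracle, 1, n - 3)
        assert steps[1].p_change == pytest.approx(p_oracle, rel=1e-9)

    def test_r2_monotone_nondecreasing(self, rng):
        n = 50
        table = pd.DataFrame(rng.normal(size=(n, 4)), columns=["y", "a", "b", "c"])
        steps = cs.hierarchical_regression(
            table, "y", [("1", ["a"]), ("2", ["b"]), ("3", ["c"])]
        )
        r2s = [s.r2 for s in steps]
        assert all(r2s[i] <= r2s[i + 1] + 1e-12 for i in range(len(r2s) - 1))

    def test_collinear_block_errors(self, rng):
        n = 30
        x = rng.normal(size=n)
        table = pd.DataFrame({"y": rng.normal(size=n), "x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            cs.hierarchical_regression(table, "y", [("a", ["x", "x2"])])

    def test_beta_std_invariant_to_rescaling(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = 3 * x + rng.normal(size=n)
        t1 = pd.DataFrame({"y": y, "x": x})
        t2 = pd.DataFrame({"y": y, "x": 1000 * x + 5})
        s1 = cs.hierarchical_regression(t1, "y", [("a", ["x"])])
        s2 = cs.hierarchical_regression(t2, "y", [("a", ["x"])])
        assert s1[0].terms.loc["x", "beta_std"] == pytest.approx(
            s2[0].terms.loc["x", "beta_std"], rel=1e-9
        )


def _moderation_table(rng, n=40, b3=32.0, noise=90.0):
    slope = rng.normal(0.0724, 0.0690, n)
    ee = rng.normal(135.0, 22.0, n)
    rt = 1259.45 - 5420.91 * slope - 4.34 * ee + b3 * slope * ee + rng.normal(0, noise, n)
    return pd.DataFrame({"mean_rt": rt, "cpp_slope": slope, "cri_leisure": ee})


class TestModeration:
    def test_conditional_effect_identity(self, rng):
        table = _moderation_table(rng)
        res = cs.moderation(table)
        b2 = res.coefficients.loc["cri_leisure", "coef"]
        b3 = res.coefficients.loc["cri_leisure:cpp_slope", "coef"]
        m = table["cpp_slope"].mean()
        sd = table["cpp_slope"].std(ddof=1)
        eff = res.conditional_effects
        assert eff.loc["mean", "effect"] == pytest.approx(b2 + b3 * m, abs=1e-12)
        assert eff.loc["mean-sd", "effect"] == pytest.approx(b2 + b3 * (m - sd), abs=1e-12)
        assert eff.loc["mean+sd", "effect"] == pytest.approx(b2 + b3 * (m + sd), abs=1e-12)

    def test_statsmodels_formula_oracle(self, rng):
        import statsmodels.formula.api as smf

        table = _moderation_table(rng)
        res = cs.moderation(table)
        ref = smf.ols("mean_rt ~ cpp_slope + cri_leisure + cri_leisure:cpp_slope", table).fit()
        assert res.coefficients.loc["cri_leisure:cpp_slope", "coef"] == pytest.approx(
            ref.params["cri_leisure:cpp_slope"], rel=1e-9
        )
        assert res.r2 == pytest.approx(ref.rsquared, rel=1e-9)

    def test_interaction_recovery_within_2se(self, rng):
        hits = 0
        for _ in range(100):
            res = cs.moderation(_moderation_table(rng))
            row = res.coefficients.loc["cri_leisure:cpp_slope"]
            hits += abs(row["coef"] - 32.0) <= 2 * row["se"]
        assert hits >= 90

    def test_covariate_supported(self, rng):
        table = _moderation_table(rng)
        table["age"] = rng.normal(72, 5, len(table))
        res = cs.moderation(table, covariates=["age"])
        assert "age" in res.coefficients.index


class TestMediation:
    def test_deterministic_chain(self):
        x = np.linspace(0, 1, 20)
        table = pd.DataFrame({"x": x, "m": x.copy(), "y": x.copy()})
        res = cs.mediation_bootstrap(table, "x", "m", "y", n_boot=500, seed=0)
        assert res.indirect == pytest.approx(1.0, abs=1e-9)
        assert res.ci_high - res.ci_low < 1e-9

    def test_reproducible_under_seed(self, rng):
        n = 30
        table = pd.DataFrame(
            {"x": rng.normal(size=n), "m": rng.normal(size=n), "y": rng.normal(size=n)}
        )
        a = cs.mediation_bootstrap(table, "x", "m", "y", n_boot=500, seed=5)
        b = cs.mediation_bootstrap(table, "x", "m", "y", n_boot=500, seed=5)
        assert (a.ci_low, a.ci_high, a.boot_se) == (b.ci_low, b.ci_high, b.boot_se)

    def test_point_estimate_matches_two_regressions(self, rng):
        import statsmodels.api as sm

        n = 50
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.7 * m + 0.2 * x + rng.normal(size=n)
        table = pd.DataFrame({"x": x, "m": m, "y": y})
        res = cs.mediation_bootstrap(table, "x", "m", "y", n_boot=100, seed=1)
        a_ref = sm.OLS(m, sm.add_constant(x)).fit().params[1]
        b_ref = sm.OLS(y, sm.add_constant(np.column_stack([x, m]))).fit().params[2]
        assert res.indirect == pytest.approx(a_ref * b_ref, rel=1e-9)

    def test_too_few_cases(self):
        table = pd.DataFrame({"x": range(5), "m": range(5), "y": range(5)})
        with pytest.raises(ValueError, match="at least 10"):
            cs.mediation_bootstrap(table, "x", "m", "y")


class TestGroupCompare:
    def test_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(1, 1, 1000)
        out = cs.group_compare(
            np.concatenate([a, b]), np.array(["a"] * 1000 + ["b"] * 1000)
        )
        assert out["F"] == pytest.approx(out["t_student"] ** 2, rel=1e-9)

    def test_equal_groups_eta_near_zero(self, rng):
        vals = rng.normal(size=400)
        out = cs.group_compare(vals, np.array(["a", "b"] * 200))
        assert out["partial_eta_sq"] < 0.02

    def test_hand_computed_three_per_group(self):
        # groups {1,2,3} and {4,5,6}: SSb = 13.5, SSw = 4, F = 13.5/(4/4) = 13.5
        vals = np.array([1.0, 2, 3, 4, 5, 6])
        grp = np.array(["a", "a", "a", "b", "b", "b"])
        out = cs.group_compare(vals, grp)
        assert out["F"] == pytest.approx(13.5, rel=1e-12)
        assert out["partial_eta_sq"] == pytest.approx(13.5 / (13.5 + 4), rel=1e-12)
        assert out["df_between"] == 1 and out["df_within"] == 4


class TestJzsBayesFactor:
    def test_t0_favors_null(self):
        vals = np.array([0.1, -0.1, 0.05, -0.05, 0.0, 0.02, -0.02, 0.0] * 3)
        vals = vals - vals.mean()  # exact t = 0
        assert cs.jzs_bf_ttest(vals) < 1.0

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t_obs, n in [(3.0, 80), (1.5, 30), (-2.2, 50), (0.0, 20)]:
            mine = cs.bf10_from_t(t_obs, n, n - 1)
            ref = float(pingouin.bayesfactor_ttest(t_obs, n, paired=True, r=0.707))
            assert mine == pytest.approx(ref, rel=1e-4)

    def test_quadrature_oracle_n80_t3(self):
        # trapezoid oracle over a dense grid with scipy's own noncentral t,
        # fully independent of the package's quad-based path
        t_obs, n = 3.0, 80
        df = n - 1
        delta = np.linspace(-2.5, 2.5, 20001)
        like = stats.nct.pdf(t_obs, df, delta * np.sqrt(n))
        prior = stats.cauchy.pdf(delta, scale=0.707)
        oracle = np.trapezoid(like * prior, delta) / stats.t.pdf(t_obs, df)
        assert cs.bf10_from_t(t_obs, n, df) == pytest.approx(oracle, rel=1e-4)

    def test_monotone_in_t(self):
        bfs = [cs.bf10_from_t(t, 40, 39) for t in (0.0, 1.0, 2.0, 3.0, 4.0)]
        assert all(b1 < b2 for b1, b2 in zip(bfs, bfs[1:]))

    def test_directional_splits(self):
        two = cs.bf10_from_t(2.0, 30, 29)
        gt = cs.bf10_from_t(2.0, 30, 29, direction="greater")
        lt = cs.bf10_from_t(2.0, 30, 29, direction="less")
        assert gt > two > lt
        assert (gt + lt) / 2 == pytest.approx(two, rel=1e-6)

    def test_independent_mode(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.8, 1, 40)
        b = rng.normal(0.0, 1, 35)
        bf = cs.jzs_bf_ttest(a, b, mode="independent")
        assert bf > 1.0

    def test_n_too_small(self):
        with pytest.raises(ValueError):
            cs.jzs_bf_ttest([1.0, 2.0])


class TestLifePercentage:
    def test_half_of_adult_life(self):
        assert cs.life_percentage(26.0, 70.0) == pytest.approx(50.0)

    def test_zero_years(self):
        assert cs.life_percentage(0.0, 45.0) == 0.0

    def test_over_100_allowed(self):
        assert cs.life_percentage(54.0, 70.0) == pytest.approx(103.846, abs=0.01)

    def test_age_at_or_below_18_errors(self):
        with pytest.raises(ValueError):
            cs.life_percentage(1.0, 18.0)
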