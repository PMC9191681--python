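"""Case-control GLMs: OLS oracle equivalence, effect-size conversion,
permutation conventions, post hoc flags, cognitive models, and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from neurosig.glm import (
    CaseControlGLM,
    _mass_ols,
    bh_fdr,
    build_design,
    cognitive_glm,
    fit_feature_glm,
    permute_group_effect,
    posthoc_contrasts,
    t_to_d,
)
from neurosig.simulate import N_CONNECTIVITY, SimulationConfig, generate_cohort
from conftest import null_config, zero_confounds


class TestEffectSizeConversion:
    def test_reference_values(self):
        """t = 5 and t = 2.5 at df = 12,203 give d = 0.09 and 0.045."""
        assert round(t_to_d(5, 12203), 2) == 0.09
        assert round(t_to_d(2.5, 12203), 3) == 0.045

    def test_zero_and_oddness(self):
        assert t_to_d(0, 100) == 0.0
        assert t_to_d(-3.2, 57) == -t_to_d(3.2, 57)

    def test_inversion_is_exact(self):
        for d, df in [(0.3, 100), (-0.8, 12203), (1.5, 7)]:
            assert t_to_d(d * np.sqrt(df) / 2, df) == pytest.approx(d, abs=1e-12)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            t_to_d(1.0, 0)


def test_mass_ols_matches_normal_equations():
    """4-row toy design: coefficients equal the textbook (X'X)^-1 X'y solution."""
    X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.5]])
    y = np.array([[0.3], [1.1], [2.2], [3.0]])
    beta, se, t, df, _ = _mass_ols(X, y)
    oracle = np.linalg.inv(X.T @ X) @ X.T @ y
    np.testing.assert_allclose(beta, oracle, rtol=1e-12)
    assert df == 2


@pytest.mark.parametrize("trial", range(10))
def test_t_statistics_match_statsmodels(trial, rng):
    """Per-feature t statistics agree with the statsmodels OLS oracle to 1e-8."""
    rng = np.random.default_rng(1000 + trial)
    n, p, m = 40, 4, 3
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    Y = rng.standard_normal((n, m))
    beta, se, t, df, _ = _mass_ols(X, Y)
    for j in range(m):
        fit = sm.OLS(Y[:, j], X).fit()
        np.testing.assert_allclose(t[:, j], fit.tvalues, rtol=1e-8)
        np.testing.assert_allclose(beta[:, j], fit.params, rtol=1e-8)
    assert df == n - p


def test_covariate_copy_feature_has_null_group_effect(small_cohort):
    """A feature lying in the covariate span leaves nothing for group to explain.

    The group coefficients are numerically zero.  (The t and F ratios are
    0/0 in exact arithmetic here, so the coefficients are the stable check;
    with a small noise floor added, group t stays at noise scale.)
    """
    cohort, conn, *_ = small_cohort
    age = cohort["age"].astype(float)
    feats = pd.DataFrame({"agecopy": age}, index=cohort.index)
    fit = fit_feature_glm(cohort, feats, panel="thickness")
    for g in fit.case_groups_:
        assert abs(fit.beta_.loc[f"group[{g}]", "agecopy"]) < 1e-8 * age.std()
    rng = np.random.default_rng(0)
    noisy = pd.DataFrame({"a": age + 1e-6 * rng.standard_normal(len(age))},
                         index=cohort.index)
    fit2 = fit_feature_glm(cohort, noisy, panel="thickness")
    assert np.abs([fit2.signature(g).iloc[0] for g in fit2.case_groups_]).max() < 4


def test_planted_d_recovered_as_t(rng):
    """d = 0.3 planted on one feature, n = 1,000/group: t near d*sqrt(df)/2."""
    eff = np.zeros(N_CONNECTIVITY)
    eff[0] = 0.3
    cfg = null_config({"CTRL": 1000, "MDD": 1000}, seed=21).replace(
        effect_map={"MDD": {"connectivity": eff}}
    )
    cohort, conn, *_ = generate_cohort(cfg)
    fit = fit_feature_glm(cohort, conn.iloc[:, :5], panel="connectivity")
    t_obs = fit.signature("MDD").iloc[0]
    t_expect = 0.3 * np.sqrt(fit.df_) / 2
    assert abs(t_obs - t_expect) < 3.0  # t has unit SE under the model


def test_null_t_statistics_follow_t_distribution():
    """Null cohort: 360 thickness t stats are t(df)-distributed (KS p > 0.001)."""
    cfg = null_config(
        {"CTRL": 250, "MDD": 125, "ANX": 125, "MDDANX": 125, "STR": 125}, seed=8
    )
    cohort, _, thick, _ = generate_cohort(cfg)
    fit = fit_feature_glm(cohort, thick, panel="thickness")
    t_all = fit.signatures().to_numpy().ravel()
    ks = stats.kstest(t_all, stats.t(fit.df_).cdf)
    assert ks.pvalue > 0.001


def test_design_errors(small_cohort):
    cohort, conn, *_ = small_cohort
    single_site = cohort.copy()
    single_site["site"] = cohort["site"].iloc[0]
    # single-level site simply contributes no columns; a truly collinear
    # design must raise and name the culprit
    dup = cohort.copy()
    dup["motion"] = dup["age"].astype(float)
    with pytest.raises(ValueError, match="motion"):
        build_design(dup, panel="connectivity")
    with pytest.raises(ValueError, match="missing columns"):
        build_design(cohort.drop(columns=["age"]), panel="thickness")
    only_ctrl = cohort[cohort["group"] == "CTRL"]
    with pytest.raises(ValueError, match="two groups"):
        build_design(only_ctrl, panel="thickness")


def test_orthogonal_prs_covariate_leaves_group_inference_unchanged(small_cohort):
    """PRS columns orthogonal to the design leave the group coefficients
    untouched (to 1e-6); t moves only through the 3-df change in the
    residual variance estimate (sub-percent here)."""
    cohort, conn, *_ = small_cohort
    cohort = cohort.copy()
    X, names, _ = build_design(cohort, panel="connectivity", with_prs=False)
    rng = np.random.default_rng(77)
    Q = np.linalg.qr(X)[0]
    for prs in ("PRS_MDD", "PRS_ANX", "PRS_PTSD"):
        v = rng.standard_normal(len(cohort))
        cohort[prs] = v - Q @ (Q.T @ v)  # orthogonal to every design column
    feats = conn.iloc[:, :10]
    f0 = fit_feature_glm(cohort, feats, panel="connectivity")
    f1 = fit_feature_glm(cohort, feats, panel="connectivity", with_prs=True)
    rows = [f"group[{g}]" for g in f0.case_groups_]
    np.testing.assert_allclose(
        f0.beta_.loc[rows].to_numpy(), f1.beta_.loc[rows].to_numpy(), atol=1e-6
    )
    np.testing.assert_allclose(
        f0.t_.loc[rows].to_numpy(), f1.t_.loc[rows].to_numpy(), atol=0.02
    )


class TestPermutation:
    def test_nperm_zero_raises(self, small_cohort):
        cohort, conn, *_ = small_cohort
        with pytest.raises(ValueError):
            permute_group_effect(cohort, conn.iloc[:, :2], n_perm=0)

    def test_extreme_observed_hits_floor(self):
        """Observed F above every null F gives p = 1/(n_perm + 1)."""
        eff = np.zeros(N_CONNECTIVITY)
        eff[0] = 2.0  # huge effect
        cfg = null_config({"CTRL": 150, "MDD": 150}, seed=2).replace(
            effect_map={"MDD": {"connectivity": eff}}
        )
        cohort, conn, *_ = generate_cohort(cfg)
        res = permute_group_effect(cohort, conn.iloc[:, :1], n_perm=100, seed=0)
        assert res.p_perm[0] == pytest.approx(1 / 101)

    def test_pvalue_convention(self):
        from neurosig.glm import _perm_pvalue

        null = np.array([[1.0], [2.0], [3.0]])
        assert _perm_pvalue(np.array([2.5]), null)[0] == pytest.approx(2 / 4)
        # ties count as >= (conservative)
        assert _perm_pvalue(np.array([3.0]), null)[0] == pytest.approx(2 / 4)

    def test_independent_mode_runs(self, small_cohort):
        cohort, conn, *_ = small_cohort
        res = permute_group_effect(
            cohort, conn.iloc[:, :3], n_perm=20, seed=1, mode="independent"
        )
        assert res.null_stats.shape == (20, 3)

    def test_freedman_lane_matches_naive_under_null(self):
        """With no covariate association, both permutation schemes give
        comparable null F distributions and p-values."""
        cfg = null_config({"CTRL": 200, "MDD": 200}, seed=6)
        cohort, conn, *_ = generate_cohort(cfg)
        feats = conn.iloc[:, :10]
        naive = permute_group_effect(cohort, feats, n_perm=100, seed=2, scheme="naive")
        fl = permute_group_effect(
            cohort, feats, n_perm=100, seed=2, scheme="freedman-lane"
        )
        np.testing.assert_allclose(naive.observed_stat, fl.observed_stat)
        assert abs(naive.null_stats.mean() - fl.null_stats.mean()) < 0.3
        with pytest.raises(ValueError, match="scheme"):
            permute_group_effect(cohort, feats, n_perm=5, scheme="bogus")


class TestPosthoc:
    def _fake_fit(self, pvals):
        fit = CaseControlGLM()
        fit.case_groups_ = ["MDD", "ANX", "MDDANX", "STR"]
        fit.p_ = pd.DataFrame(
            np.array(pvals)[:, None], index=[f"group[{g}]" for g in fit.case_groups_],
            columns=["f1"],
        )
        return fit

    def test_all_at_0_02_none_flagged(self):
        flags = posthoc_contrasts(self._fake_fit([0.02] * 4), alpha=0.0125)
        assert not flags.to_numpy().any()

    def test_exactly_one_flag(self):
        flags = posthoc_contrasts(self._fake_fit([0.001, 0.02, 0.5, 0.9]), alpha=0.0125)
        assert flags.to_numpy().sum() == 1

    def test_alpha_one_flags_all(self):
        flags = posthoc_contrasts(self._fake_fit([0.3, 0.6, 0.99, 0.0125]), alpha=1.0)
        assert flags.to_numpy().all()


class TestBHFDR:
    @staticmethod
    def _bh_oracle(p, q):
        """Brute-force step-up: largest k with p_(k) <= k q / m; reject those."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_star = k
        reject = np.zeros(m, bool)
        reject[order[:k_star]] = True
        return reject

    def test_known_step_up_cases(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05).all()
        assert not bh_fdr([1.0, 1.0, 1.0], q=0.05).any()
        assert bh_fdr([0.04], q=0.05).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40)) ** rng.uniform(0.5, 3)
        np.testing.assert_array_equal(bh_fdr(p, 0.05), self._bh_oracle(p, 0.05))

    def test_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(size=30))
        rej = bh_fdr(p, 0.1)
        # rejections form a prefix of the sorted p-values
        assert not np.any(np.diff(rej.astype(int)) > 0)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCognitiveGLM:
    def test_planted_deficit_recovered(self):
        """A -0.28 SD DSST deficit (the study's largest) is recovered within 3 SE."""
        cfg = null_config(
            {"CTRL": 2000, "MDDANX": 2000}, seed=13, cognition_missing_rate=0.0
        ).replace(
            effect_map={"MDDANX": {"cognition": np.array([0.0, 0.0, 0.0, -0.28])}}
        )
        cohort, *_, cog = generate_cohort(cfg)
        res = cognitive_glm(cohort, cog)
        beta = res.beta.loc["MDDANX", "DSST"]
        se = res.se.loc["MDDANX", "DSST"]
        assert abs(beta - (-0.28)) < 3 * se

    def test_null_betas_near_zero(self):
        cfg = null_config({"CTRL": 1500, "MDD": 1500}, seed=14, cognition_missing_rate=0.0)
        cohort, *_, cog = generate_cohort(cfg)
        res = cognitive_glm(cohort, cog)
        assert np.abs(res.beta.to_numpy()).max() < 0.1

    def test_complete_case_restriction(self, small_cohort):
        cohort, _, _, cog = small_cohort
        res = cognitive_glm(cohort, cog)
        assert res.n == int(cog.notna().all(axis=1).sum())

    def test_zero_variance_test_raises(self, small_cohort):
        cohort, _, _, cog = small_cohort
        bad = cog.copy()
        bad["Gf"] = 1.0
        with pytest.raises(ValueError, match="Gf"):
            cognitive_glm(cohort, bad)

    def test_fdr_flags_shape(self, small_cohort):
        cohort, _, _, cog = small_cohort
        res = cognitive_glm(cohort, cog)
        flags = res.fdr_flags(0.05)
        assert flags.shape == res.p.shape
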