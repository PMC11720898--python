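"""Cross-subject GLMs, FWE correction, and effect sizes."""

import numpy as np
import pandas as pd
import pytest

from dfnckit.stats import (
    effect_sizes,
    fit_glm,
    fwe_correct,
    run_analysis,
    select_subgroup,
    validate_cohort,
)


def make_table(n, seed=0, group="term", pna_max=4.0):
    rng = np.random.default_rng(seed)
    ga = rng.uniform(37, 44, n)
    pna = rng.uniform(0, pna_max, n)
    return pd.DataFrame({
        "subject": [f"s{i:03d}" for i in range(n)],
        "ga_weeks": ga,
        "pna_weeks": pna,
        "pma_weeks": ga + pna,
        "sex": np.where(np.arange(n) % 2 == 0, "M", "F"),
        "group": group,
        "mean_fd": rng.uniform(0.05, 0.4, n),
    })


def ols_oracle(y, X):
    """Normal-equations OLS with t for the first non-intercept column."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    resid = y - Xd @ beta
    df = len(y) - Xd.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    t = beta[1] / np.sqrt(cov[1, 1])
    return beta[1], t, df


class TestFitGLM:
    def test_exact_linear_relation(self):
        t = make_table(40, seed=1)
        y = 3.0 + 2.0 * t.ga_weeks.to_numpy()
        res = fit_glm(y, t, "ga")
        assert res.beta == pytest.approx(2.0)
        assert abs(res.p) < 1e-12

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for seed in range(20):
            t = validate_cohort(make_table(30, seed=seed))
            y = rng.normal(size=30)
            res = fit_glm(y, t, "ga")
            X = t[["ga_weeks", "sex_code", "mean_fd"]].to_numpy()
            b, tt, df = ols_oracle(y, X)
            assert res.beta == pytest.approx(b, rel=1e-8)
            assert res.t == pytest.approx(tt, rel=1e-8)
            assert res.df == df

    def test_type_one_error_at_nominal_level(self):
        """Null outcomes: rejection rate at alpha=0.05 is 0.05 +/- 0.015."""
        rng = np.random.default_rng(3)
        t = validate_cohort(make_table(50, seed=3))
        rejections = sum(
            fit_glm(rng.standard_normal(50), t, "ga").p < 0.05 for _ in range(1000)
        )
        assert rejections / 1000 == pytest.approx(0.05, abs=0.015)

    def test_slope_coverage_near_nominal(self):
        """95% CI covers an injected slope in ~95% of replicate cohorts."""
        rng = np.random.default_rng(4)
        t = validate_cohort(make_table(60, seed=4))
        ga = t.ga_weeks.to_numpy()
        hits = 0
        for _ in range(300):
            y = 0.02 * ga + 0.1 * rng.standard_normal(60)
            lo, hi = fit_glm(y, t, "ga").conf_int()
            hits += lo <= 0.02 <= hi
        assert hits / 300 == pytest.approx(0.95, abs=0.04)

    def test_collinear_design_rejected(self):
        t = make_table(30, seed=5)
        t["mean_fd"] = 0.2  # constant column -> collinear with intercept
        with pytest.raises(ValueError, match="collinear"):
            fit_glm(np.random.default_rng(5).normal(size=30), t, "ga")

    def test_too_few_subjects_rejected(self):
        t = make_table(4, seed=6)
        with pytest.raises(ValueError, match="too small"):
            fit_glm(np.zeros(4), t, "ga")


class TestFWE:
    def test_single_p_unchanged(self):
        p_adj, _ = fwe_correct(np.array([0.03]))
        assert p_adj[0] == pytest.approx(0.03)

    def test_bonferroni_family_of_five(self):
        p_adj, sig = fwe_correct(np.array([0.01, 0.5, 0.2, 0.9, 0.04]))
        assert p_adj[0] == pytest.approx(0.05)
        assert not sig[0]  # 0.05 is not < 0.05

    def test_familywise_error_controlled_under_null(self):
        """All-null families of 136 edges: FWER <= 0.05 (with MC slack)."""
        rng = np.random.default_rng(7)
        fw = sum(
            fwe_correct(rng.uniform(1e-12, 1, 136))[1].any() for _ in range(1000)
        )
        assert fw / 1000 <= 0.05 + 0.02

    def test_monotone_in_family_size(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, 50)
        _, sig_big = fwe_correct(p)
        _, sig_small = fwe_correct(p[:10])
        assert (sig_small | ~sig_big[:10]).all()  # significant at m=50 => at m=10

    def test_maxt_permutation_variant(self):
        rng = np.random.default_rng(9)
        t_obs = np.array([6.0, 0.5])
        null_t = rng.standard_normal((999, 2))
        p_adj, sig = fwe_correct(
            np.array([1e-8, 0.6]), method="maxt", t_values=t_obs, null_t=null_t
        )
        assert sig[0] and not sig[1]
        assert p_adj[0] == pytest.approx(1 / 1000)


# all rows of the published group-contrast table: (t, d, r) at n1 = n2 = 36
GROUP_CONTRAST_ROWS = [
    (5.44, 1.30, 0.55), (-3.23, -0.77, 0.36), (-5.77, -1.38, 0.57),
    (-6.15, -1.47, 0.59), (-5.73, -1.37, 0.57), (-6.06, -1.45, 0.59),
    (-5.95, -1.42, 0.58), (-6.95, -1.66, 0.64), (-5.97, -1.43, 0.58),
    (-4.69, -1.12, 0.49), (-5.44, -1.30, 0.55), (-5.49, -1.31, 0.55),
    (-6.17, -1.47, 0.59), (-6.44, -1.54, 0.61), (-6.24, -1.49, 0.60),
    (-4.93, -1.18, 0.51), (-5.59, -1.34, 0.56), (-5.61, -1.34, 0.56),
    (-5.54, -1.32, 0.55),
]


class TestEffectSizes:
    @pytest.mark.parametrize("t, d, r", GROUP_CONTRAST_ROWS)
    def test_published_group_contrasts(self, t, d, r):
        es = effect_sizes(t, 36, 36)
        assert round(es.cohens_d, 2) == pytest.approx(d)
        assert round(es.effect_r, 2) == pytest.approx(r)

    def test_zero_t(self):
        es = effect_sizes(0.0, 36, 36)
        assert es.cohens_d == 0.0 and es.effect_r == 0.0

    def test_sign_and_bounds(self):
        es = effect_sizes(-4.0, 20, 25)
        assert es.cohens_d < 0
        assert 0 <= es.effect_r < 1

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            effect_sizes(2.0, 1, 36)


class TestRunAnalysis:
    def test_ga_subgroup_filters_pna(self):
        t = make_table(60, seed=10, pna_max=3.0)
        sub = select_subgroup(t, "ga", pna_max=1.0)
        assert (sub.pna_weeks < 1.0).all()
        assert len(sub) < 60

    def test_pna_subgroup_filters_ga_window(self):
        t = make_table(80, seed=11)
        sub = select_subgroup(t, "pna", ga_target=40.0, ga_tol=0.5)
        assert ((sub.ga_weeks >= 39.5) & (sub.ga_weeks < 40.5)).all()

    def test_injected_effect_signs_recovered(self):
        """Negative GA effect on static FNC + positive on variance."""
        rng = np.random.default_rng(12)
        t = make_table(100, seed=12, pna_max=0.9)
        ga_c = t.ga_weeks.to_numpy() - 40.5
        sfnc = 0.3 - 0.02 * ga_c + 0.02 * rng.standard_normal(100)
        var = 0.01 + 0.001 * ga_c + 0.0008 * rng.standard_normal(100)
        res = run_analysis(t, {"sfnc_whole": sfnc, "var_whole": var}, model="ga")
        by = res.set_index("level")
        assert by.loc["sfnc_whole", "t"] < 0 and by.loc["sfnc_whole", "significant"]
        assert by.loc["var_whole", "t"] > 0 and by.loc["var_whole", "significant"]

    def test_group_model_reports_effect_sizes(self):
        rng = np.random.default_rng(13)
        t = pd.concat(
            [make_table(36, seed=13), make_table(36, seed=14, group="preterm")],
            ignore_index=True,
        )
        y = 0.2 - 0.05 * (t.group == "preterm").to_numpy() + 0.03 * rng.standard_normal(72)
        res = run_analysis(t, {"whole": y}, model="group")
        row = res.iloc[0]
        assert row.t < 0
        assert np.isfinite(row.d) and np.isfinite(row.r)
        assert np.sign(row.d) == np.sign(row.t) and 0 <= row.r < 1

    def test_tiny_subgroup_rejected(self):
        t = make_table(6, seed=15)
        with pytest.raises(ValueError, match="subgroup"):
            run_analysis(t, {"whole": np.zeros(6)}, model="ga")
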