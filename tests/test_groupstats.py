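"""Mixed models with crossed random intercepts, LRTs, t tests, R²."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from loclab import groupstats as G


def _small_data(seed=0, **kw):
    defaults = dict(
        n_subjects=4, n_frois=2, condition_beta=1.0,
        subject_sd=0.5, froi_sd=0.3, residual_sd=0.4, seed=seed,
    )
    defaults.update(kw)
    return G.simulate_crossed_data(**defaults)


SPEC_ADD = G.MixedModelSpec(
    response="response",
    fixed=("condition", "version"),
    random_intercepts=("subject", "froi"),
)
SPEC_FULL = G.MixedModelSpec(
    response="response",
    fixed=("condition", "version", "condition:version"),
    random_intercepts=("subject", "froi"),
)


def independent_ml_loglik(data, spec):
    """Independent oracle: maximize the non-profiled Gaussian likelihood
    over (τ₁², τ₂², σ²) with Nelder–Mead, building the dense covariance
    V = σ²I + τ₁²Z₁Z₁ᵀ + τ₂²Z₂Z₂ᵀ directly."""
    y = data[spec.response].to_numpy(float)
    names, X = G._fixed_design(data, spec.fixed)
    Zs = [G._grouping(data, g) for g in spec.random_intercepts]
    n = len(y)

    def minus_ll(log_theta):
        tau1, tau2, s2 = np.exp(log_theta)
        V = s2 * np.eye(n) + tau1 * Zs[0] @ Zs[0].T + tau2 * Zs[1] @ Zs[1].T
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        from scipy.linalg import solve_triangular

        Xw = solve_triangular(L, X, lower=True)
        yw = solve_triangular(L, y, lower=True)
        beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        r = yw - Xw @ beta
        logdet = 2.0 * np.log(np.diag(L)).sum()
        return 0.5 * (n * np.log(2 * np.pi) + logdet + r @ r)

    best = np.inf
    for x0 in ([np.log(0.2)] * 3, [np.log(1.0)] * 3, [-3.0, -3.0, np.log(0.2)]):
        res = optimize.minimize(minus_ll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return -best


class TestFitLMM:
    def test_zero_variance_components_collapse_to_ols(self):
        data = _small_data(seed=1, n_subjects=6, n_frois=3, subject_sd=0.0, froi_sd=0.0)
        res = G.fit_lmm(data, SPEC_ADD)
        names, X = G._fixed_design(data, SPEC_ADD.fixed)
        beta_ols = np.linalg.lstsq(X, data["response"].to_numpy(), rcond=None)[0]
        for name, b in zip(names, beta_ols):
            assert res.beta[name] == pytest.approx(b, abs=1e-3)
        assert res.boundary

    def test_ml_loglik_matches_independent_oracle(self):
        data = _small_data(seed=2)
        spec = G.MixedModelSpec(
            response="response", fixed=("condition",),
            random_intercepts=("subject", "froi"), estimation="ML",
        )
        res = G.fit_lmm(data, spec)
        oracle = independent_ml_loglik(data, spec)
        assert res.loglik == pytest.approx(oracle, abs=1e-4)

    def test_matches_statsmodels_crossed_reml(self):
        """Cross-check against statsmodels MixedLM (crossed intercepts via
        variance components in a single group)."""
        import statsmodels.formula.api as smf

        data = _small_data(seed=3, n_subjects=6, n_frois=3)
        data = data[data.version == "standard"].copy()
        spec = G.MixedModelSpec(
            response="response", fixed=("condition",),
            random_intercepts=("subject", "froi"),
        )
        res = G.fit_lmm(data, spec)
        data["one"] = 1
        sm_fit = smf.mixedlm(
            "response ~ C(condition)", data, groups="one",
            vc_formula={"subject": "0 + C(subject)", "froi": "0 + C(froi)"},
        ).fit(reml=True)
        cond_name = [n for n in res.beta if n.startswith("condition")][0]
        sm_cond = [n for n in sm_fit.params.index if "condition" in n][0]
        assert res.beta[cond_name] == pytest.approx(sm_fit.params[sm_cond], abs=1e-4)
        assert res.se[cond_name] == pytest.approx(sm_fit.bse[sm_cond], rel=1e-3)

    def test_single_dataset_recovery_within_three_se(self):
        data = G.simulate_crossed_data(
            n_subjects=24, n_frois=5, condition_beta=1.5,
            subject_sd=0.5, froi_sd=0.3, residual_sd=0.4, seed=4,
        )
        res = G.fit_lmm(data, SPEC_ADD)
        b = res.beta["condition[sentences]"]
        assert abs(b - 1.5) < 3.0 * res.se["condition[sentences]"]
        # variance components in the right neighbourhood
        assert res.variance_components["subject"] == pytest.approx(0.25, abs=0.2)

    def test_row_permutation_invariance(self):
        data = _small_data(seed=5)
        res1 = G.fit_lmm(data, SPEC_ADD)
        shuffled = data.sample(frac=1.0, random_state=99).reset_index(drop=True)
        res2 = G.fit_lmm(shuffled, SPEC_ADD)
        for name in res1.beta:
            assert res1.beta[name] == pytest.approx(res2.beta[name], abs=1e-8)

    def test_satterthwaite_df_reasonable(self):
        data = _small_data(seed=6, n_subjects=8, n_frois=4)
        res = G.fit_lmm(data, SPEC_ADD, p_method="satterthwaite")
        df = res.dof_satterthwaite["condition[sentences]"]
        assert 2.0 < df < res.n_obs

    def test_wald_t_converges_to_ols_t_without_variance_components(self):
        data = _small_data(seed=7, n_subjects=8, n_frois=4, subject_sd=0.0, froi_sd=0.0)
        res = G.fit_lmm(data, SPEC_ADD)
        names, X = G._fixed_design(data, SPEC_ADD.fixed)
        y = data["response"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        s2 = r @ r / (len(y) - X.shape[1])
        se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
        i = names.index("condition[sentences]")
        t_ols = beta[i] / se[i]
        assert res.t["condition[sentences]"] == pytest.approx(t_ols, rel=0.02)


class TestLRT:
    def test_identical_specs_give_zero_chisq(self):
        data = _small_data(seed=8)
        res = G.lrt_interaction(data, SPEC_ADD, SPEC_ADD)
        assert res.chisq == 0.0
        assert res.p == 1.0

    def test_non_nested_rejected(self):
        other = G.MixedModelSpec(
            response="response", fixed=("condition:version",),
            random_intercepts=("subject", "froi"),
        )
        with pytest.raises(ValueError, match="nest"):
            G.lrt_interaction(_small_data(), SPEC_ADD, other)

    def test_detects_injected_interaction(self):
        data = G.simulate_crossed_data(
            n_subjects=16, n_frois=5, condition_beta=1.5, interaction_beta=0.7,
            subject_sd=0.3, froi_sd=0.2, residual_sd=0.4, seed=9,
        )
        res = G.lrt_interaction(data, SPEC_FULL, SPEC_ADD)
        assert res.df == 1
        assert res.chisq > 0
        assert res.p < 1e-4


class TestClassicalTTests:
    def test_identical_paired_vectors(self):
        t, p = G.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_one_sample_mean_equals_null(self):
        t, _p = G.one_sample_t([1, 2, 3, 4, 5], mu0=3.0)
        assert t == 0.0

    def test_hand_computed_paired_t(self):
        """diffs [1,2,0,3]: mean 1.5, s² = 5/3, t = 1.5/(√(5/3)/2) = 2.3238."""
        x = np.array([2.0, 4.0, 1.0, 6.0])
        y = x - np.array([1.0, 2.0, 0.0, 3.0])
        t, p = G.paired_t(x, y)
        assert t == pytest.approx(1.5 / (np.sqrt(5.0 / 3.0) / 2.0), abs=1e-6)
        assert t == pytest.approx(2.3238, abs=1e-4)
        # agreement with scipy's implementation
        sp = stats.ttest_rel(x, y)
        assert t == pytest.approx(sp.statistic) and p == pytest.approx(sp.pvalue)

    def test_degenerate_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            G.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


class TestMixedR2:
    def test_zero_fixed_effects_give_zero_marginal_r2(self):
        data = _small_data(seed=10, condition_beta=0.0)
        spec = G.MixedModelSpec(
            response="response", fixed=("condition",),
            random_intercepts=("subject", "froi"),
        )
        res = G.fit_lmm(data, spec)
        r2m, r2c = G.mixed_r2(res)
        assert r2m < 0.02
        assert r2m <= r2c <= 1.0

    def test_variance_decomposition_oracle(self):
        """R² recomputed from scratch from the fitted pieces."""
        data = _small_data(seed=11, n_subjects=8, n_frois=3)
        res = G.fit_lmm(data, SPEC_ADD)
        names, X = G._fixed_design(data, SPEC_ADD.fixed)
        pred = X @ np.array([res.beta[n] for n in names])
        var_f = np.var(pred)
        tau = [res.variance_components[g] for g in ("subject", "froi")]
        s2 = res.variance_components["residual"]
        r2m = var_f / (var_f + sum(tau) + s2)
        r2c = (var_f + sum(tau)) / (var_f + sum(tau) + s2)
        assert res.r2_marginal == pytest.approx(r2m, abs=1e-6)
        assert res.r2_conditional == pytest.approx(r2c, abs=1e-6)


class TestFormulaParsing:
    def test_full_formula(self):
        spec = G.parse_formula(
            "response ~ condition * version + (1|participant) + (1|froi)"
        )
        assert spec.fixed == ("condition", "version", "condition:version")
        assert spec.random_intercepts == ("participant", "froi")
        assert spec.response == "response"

    def test_random_slope_rejected(self):
        with pytest.raises(ValueError, match="random intercepts"):
            G.parse_formula("y ~ a + (a|subject)")
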