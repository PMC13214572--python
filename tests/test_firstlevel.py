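"""First-level GLM: HRF, design matrix, prewhitened fit vs. dense GLS
oracle, contrasts, smoothing."""

import numpy as np
import pytest

from loclab import firstlevel as F
from loclab.io import LooseSchedule, _EventConditions
from loclab.paradigm import TimedEvent

from .conftest import ar1_covariance, dense_gls, percent_scale, toy_design


class TestCanonicalHRF:
    def test_peak_near_five_seconds(self):
        """Dense-grid maximization of the double-gamma: the default
        kernel (peak delay 6 s, dispersion 1 s) peaks at (a−1)·scale = 5 s."""
        dt = 0.001
        h = F.canonical_hrf(dt)
        assert abs(dt * np.argmax(h) - 5.0) <= dt + 1e-9

    def test_zero_at_origin_and_unit_peak(self):
        h = F.canonical_hrf(0.01)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_grid_refinement_consistency(self):
        """Halving dt reproduces coarse-grid values at shared times."""
        coarse = F.canonical_hrf(0.2)
        fine = F.canonical_hrf(0.1)
        assert np.allclose(fine[::2], coarse, atol=1e-9)

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            F.HRFParams(peak_dispersion_s=0.0)


class TestDesignMatrix:
    @pytest.mark.parametrize(
        "n_scans,tr,cutoff",
        [(179, 2.0, 128.0), (107, 2.0, 128.0), (224, 2.0, 128.0), (100, 1.5, 96.0)],
    )
    def test_drift_column_count_by_enumeration(self, n_scans, tr, cutoff):
        """Number of DCT drift columns equals the count of components
        with full period 2T/k at or above the cutoff (inclusive at the
        boundary, as in the SPM/nilearn convention), enumerated directly."""
        T = n_scans * tr
        expected = sum(1 for k in range(1, n_scans) if 2 * T / k >= cutoff)
        assert F.n_drift_columns(n_scans, tr, cutoff) == expected
        assert F.dct_drift_basis(n_scans, tr, cutoff).shape == (n_scans, expected)

    def test_drift_count_matches_nilearn(self):
        """Independent cross-check against nilearn's cosine drift basis."""
        from nilearn.glm.first_level.design_matrix import create_cosine_drift

        for n_scans, tr in ((179, 2.0), (107, 2.0)):
            frame_times = np.arange(n_scans) * tr
            dm = create_cosine_drift(1.0 / 128.0, frame_times)
            n_nilearn = dm.shape[1] - 1  # last column is the constant
            assert F.n_drift_columns(n_scans, tr, 128.0) == n_nilearn

    def test_structure(self, standard_schedule):
        X = F.build_design_matrix(standard_schedule, 179, 2.0)
        assert set(X.condition_columns) == {"sentences", "nonwords"}
        assert "fixation" not in X.names
        assert X.names.count("constant") == 1
        assert "sentences_derivative" in X.names
        assert np.linalg.matrix_rank(X.values) == X.values.shape[1]

    def test_condition_columns_orthogonal_to_constant_after_drift_projection(
        self, standard_schedule
    ):
        X = F.build_design_matrix(standard_schedule, 179, 2.0)
        nuis = X.values[:, [i for i, n in enumerate(X.names) if n.startswith("drift") or n == "constant"]]
        proj = nuis @ np.linalg.lstsq(nuis, X.values, rcond=None)[0]
        resid = X.values - proj
        for cond, col in X.condition_columns.items():
            assert abs(resid[:, col] @ np.ones(179)) < 1e-9

    def test_collinear_design_raises_rank_error(self, standard_schedule):
        nuisance = np.ones((179, 1))  # duplicates the constant column
        with pytest.raises(F.RankError, match="collinear"):
            F.build_design_matrix(standard_schedule, 179, 2.0, nuisance=nuisance)

    def test_schedule_too_short_rejected(self, speeded_schedule):
        with pytest.raises(ValueError):
            F.build_design_matrix(speeded_schedule, 500, 2.0)

    def test_hrf_sampling_convention_shared_with_regressor(self):
        """A single short event regressor reproduces the HRF shape."""
        ev = TimedEvent(onset_s=0.0, duration_s=0.1, condition="c", block_index=0)
        sched = LooseSchedule(
            version=_EventConditions(conditions=("c",)),
            events=(ev,),
            total_duration_s=64.0,
        )
        reg = F.condition_regressor(sched, "c", 32, 2.0, dt_s=0.1)
        h = F.canonical_hrf(0.1)
        expected = h[::20][:16] / np.max(np.abs(h[::20][:16]))
        assert np.allclose(reg[:16], expected, atol=1e-9)


class TestFitGLM:
    def test_zero_ar_equals_ols(self):
        rng = np.random.default_rng(0)
        X = toy_design(30, 2, rng)
        y = rng.standard_normal((30, 5)) + 10.0
        fit = F.fit_glm(y, X, F.GLMOptions(ar_coef=0.0))
        beta_ols = np.linalg.lstsq(X.values, percent_scale(y), rcond=None)[0]
        assert np.allclose(fit.beta.T, beta_ols, atol=1e-10)

    def test_whitened_fit_matches_dense_gls_oracle(self):
        """Prewhitened OLS equals GLS with the explicit AR(1) covariance
        inverse, across random toy problems."""
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(20):
            n = int(rng.integers(15, 40))
            X = toy_design(n, int(rng.integers(1, 4)), rng)
            y = rng.standard_normal(n) + 5.0
            fit = F.fit_glm(y[:, None], X)
            ys = percent_scale(y[:, None])[:, 0]
            beta, t, _ = dense_gls(ys, X.values, 0.2)
            worst = max(worst, np.max(np.abs(fit.beta[0] - beta)))
        assert worst < 1e-8

    def test_t_matches_gls_marginal_t(self):
        rng = np.random.default_rng(2)
        n = 25
        X = toy_design(n, 2, rng)
        y = rng.standard_normal(n) + 5.0
        fit = F.fit_glm(y[:, None], X)
        cmap = F.contrast(fit, {"cond": 1.0})
        ys = percent_scale(y[:, None])[:, 0]
        _, t_oracle, _ = dense_gls(ys, X.values, 0.2)
        assert cmap.t[0] == pytest.approx(t_oracle[0], abs=1e-8)

    def test_drift_span_invariance(self, speeded_schedule):
        """Adding any vector in the drift span leaves condition contrasts
        unchanged (drift columns have zero mean, so percent scaling is
        unaffected)."""
        rng = np.random.default_rng(3)
        n = 107
        X = F.build_design_matrix(speeded_schedule, n, 2.0)
        y = 1000.0 + rng.standard_normal((n, 4))
        drift = F.dct_drift_basis(n, 2.0, 128.0)
        y2 = y + 50.0 * drift[:, [0]] - 30.0 * drift[:, [1]]
        c1 = F.contrast(F.fit_glm(y, X), {"sentences": 1, "nonwords": -1})
        c2 = F.contrast(F.fit_glm(y2, X), {"sentences": 1, "nonwords": -1})
        assert np.allclose(c1.effect, c2.effect, atol=1e-8)

    def test_baseline_invariance(self, speeded_schedule):
        rng = np.random.default_rng(4)
        n = 107
        X = F.build_design_matrix(speeded_schedule, n, 2.0)
        y = 1000.0 + rng.standard_normal((n, 4))
        c1 = F.contrast(F.fit_glm(y, X), {"sentences": 1, "nonwords": -1})
        c2 = F.contrast(F.fit_glm(y * 7.5, X), {"sentences": 1, "nonwords": -1})
        assert np.allclose(c1.effect, c2.effect, atol=1e-8)

    def test_nonfinite_data_rejected(self):
        rng = np.random.default_rng(5)
        X = toy_design(20, 1, rng)
        y = rng.standard_normal((20, 2))
        y[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            F.fit_glm(y, X)


class TestContrast:
    def test_antisymmetry_and_scale_invariance(self):
        rng = np.random.default_rng(6)
        n = 30
        cols = [rng.standard_normal(n), rng.standard_normal(n), np.ones(n)]
        X = F.DesignMatrix(
            values=np.column_stack(cols),
            names=("a", "b", "constant"),
            condition_columns={"a": 0, "b": 1},
            nuisance_columns=(2,),
            tr_s=2.0,
        )
        # exact construction: both condition betas equal
        y = (100.0 + 2.0 * cols[0] + 2.0 * cols[1])[:, None] * np.ones((1, 3))
        fit = F.fit_glm(y, X)
        c1 = F.contrast(fit, {"a": 1.0, "b": -1.0})
        assert np.abs(c1.effect).max() < 1e-8
        y2 = y + rng.standard_normal((n, 3))
        fit2 = F.fit_glm(y2, X)
        d1 = F.contrast(fit2, {"a": 1.0, "b": -1.0})
        d2 = F.contrast(fit2, {"a": 2.0, "b": -2.0})
        assert np.allclose(d2.effect, 2.0 * d1.effect)
        assert np.allclose(d2.t, d1.t)

    def test_unknown_condition_rejected(self):
        rng = np.random.default_rng(7)
        X = toy_design(20, 1, rng)
        fit = F.fit_glm(rng.standard_normal((20, 2)) + 5, X)
        with pytest.raises(KeyError):
            F.contrast(fit, {"nope": 1.0})


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(8)
        vol = rng.standard_normal((6, 6, 6))
        assert F.gaussian_smooth(vol, 0.0, 2.0) is vol

    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 8), 3.25)
        out = F.gaussian_smooth(vol, 4.0, 2.0)
        assert np.allclose(out, 3.25, atol=1e-9)

    def test_impulse_ratio_matches_closed_form(self):
        """Center/neighbor ratio of a smoothed impulse equals the
        Gaussian kernel ratio exp(1/(2σ_vox²)) within 1%."""
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        fwhm, voxel = 4.0, 2.0
        out = F.gaussian_smooth(vol, fwhm, voxel)
        sigma_vox = fwhm * F.FWHM_TO_SIGMA / voxel
        expected = np.exp(1.0 / (2.0 * sigma_vox**2))
        assert out[7, 7, 7] / out[8, 7, 7] == pytest.approx(expected, rel=0.01)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            F.gaussian_smooth(np.zeros((4, 4, 4)), -1.0, 2.0)
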