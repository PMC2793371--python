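"""GLM fitting, F-contrasts and the model-comparison machinery."""

import numpy as np
import pytest
from scipy import stats

import eegbold as eb
from eegbold.design import BOLDDataset, DesignMatrix


def _plain_design(X, n_interest, TR=3.06, highpass=None):
    """Wrap a raw matrix as a design whose last column is the confound mean."""
    labels = [f"c{i}" for i in range(X.shape[1])]
    return DesignMatrix(
        X=X,
        column_labels=labels,
        partition={"interest": np.arange(n_interest)},
        confound_columns=np.arange(n_interest, X.shape[1]),
        session_boundaries=[],
        TR=TR,
        highpass_cutoff=highpass,
    )


@pytest.fixture()
def noise_design(rng):
    n, p = 120, 6
    X = np.column_stack([np.random.default_rng(0).standard_normal((n, p - 1)), np.ones(n)])
    return _plain_design(X, n_interest=3)


class TestFitGLM:
    def test_noiseless_recovery(self, noise_design):
        rng = np.random.default_rng(1)
        beta_true = rng.standard_normal((noise_design.X.shape[1], 8))
        Y = noise_design.X @ beta_true
        fit = eb.fit_glm(Y, noise_design)
        np.testing.assert_allclose(fit.beta, beta_true, atol=1e-8)
        np.testing.assert_allclose(fit.residual_ss, 0.0, atol=1e-12)

    def test_scan_count_mismatch(self, noise_design):
        with pytest.raises(ValueError, match="mismatch"):
            eb.fit_glm(np.zeros((10, 3)), noise_design)

    def test_rank_deficiency_adjusts_df(self, noise_design):
        X = noise_design.X
        Xdup = np.column_stack([X[:, :3], X[:, 2], X[:, 3:]])
        dm = _plain_design(Xdup, n_interest=4)
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((X.shape[0], 4))
        fit_full = eb.fit_glm(Y, noise_design)
        fit_dup = eb.fit_glm(Y, dm)
        assert fit_dup.rank == fit_full.rank
        assert fit_dup.df_residual == fit_full.df_residual
        np.testing.assert_allclose(fit_dup.residual_ss, fit_full.residual_ss, rtol=1e-9)

    def test_ar1_prewhitening_estimates_pooled_rho(self, noise_design):
        rng = np.random.default_rng(3)
        n = noise_design.X.shape[0]
        eps = rng.standard_normal((n, 200))
        from scipy.signal import lfilter

        Y = lfilter([1.0], [1.0, -0.5], eps, axis=0)
        fit = eb.fit_glm(Y, noise_design, ar1_prewhiten=True)
        assert fit.ar1_rho == pytest.approx(0.5, abs=0.07)


class TestFContrast:
    def test_orthogonal_columns_give_zero_f(self):
        n = 80
        t = np.arange(n)
        X = np.column_stack([np.cos(2 * np.pi * t / 10), np.ones(n)])
        dm = _plain_design(X, n_interest=1)
        Y = np.cos(2 * np.pi * t / 4)[:, None]  # orthogonal-ish to the tested column
        fit = eb.fit_glm(Y, dm)
        fr = eb.f_contrast(fit, dm.partition["interest"])
        assert fr.F[0] < 0.05

    def test_equals_reduced_model_refit_oracle(self, rng):
        """Brute-force full-vs-reduced refit on a 50-voxel synthetic set."""
        n, p_int, p_conf, v = 90, 5, 3, 50
        g = np.random.default_rng(7)
        X = np.column_stack([g.standard_normal((n, p_int + p_conf - 1)), np.ones(n)])
        dm = _plain_design(X, n_interest=p_int)
        beta = g.standard_normal((X.shape[1], v)) * 0.3
        Y = X @ beta + g.standard_normal((n, v))
        fit = eb.fit_glm(Y, dm)
        fr = eb.f_contrast(fit, dm.partition["interest"])

        X_red = X[:, p_int:]
        b_red, *_ = np.linalg.lstsq(X_red, Y, rcond=None)
        rss_red = ((Y - X_red @ b_red) ** 2).sum(axis=0)
        df1 = p_int
        df2 = n - np.linalg.matrix_rank(X)
        F_oracle = ((rss_red - fit.residual_ss) / df1) / (fit.residual_ss / df2)
        np.testing.assert_allclose(fr.F, F_oracle, atol=1e-8, rtol=1e-8)
        assert fr.df == (df1, df2)

    def test_single_column_f_equals_t_squared(self):
        g = np.random.default_rng(8)
        n = 60
        X = np.column_stack([g.standard_normal(n), np.ones(n)])
        dm = _plain_design(X, n_interest=1)
        Y = (0.4 * X[:, 0] + g.standard_normal(n))[:, None]
        fit = eb.fit_glm(Y, dm)
        fr = eb.f_contrast(fit, [0])
        res = stats.linregress(X[:, 0], Y[:, 0])
        t_stat = res.slope / res.stderr
        assert fr.F[0] == pytest.approx(t_stat**2, rel=1e-8)

    def test_invariant_to_reparameterization_of_tested_set(self):
        g = np.random.default_rng(9)
        n = 70
        A = g.standard_normal((n, 3))
        conf = np.ones((n, 1))
        Y = g.standard_normal((n, 10)) + A @ g.standard_normal((3, 10))
        M = g.standard_normal((3, 3)) + 3 * np.eye(3)  # invertible mix
        f1 = eb.f_contrast(
            eb.fit_glm(Y, _plain_design(np.column_stack([A, conf]), 3)), [0, 1, 2]
        )
        f2 = eb.f_contrast(
            eb.fit_glm(Y, _plain_design(np.column_stack([A @ M, conf]), 3)), [0, 1, 2]
        )
        np.testing.assert_allclose(f1.F, f2.F, rtol=1e-8)

    def test_confound_overlap_rejected(self, noise_design):
        fit = eb.fit_glm(np.random.default_rng(0).standard_normal((120, 2)), noise_design)
        with pytest.raises(ValueError, match="confound"):
            eb.f_contrast(fit, [2, 4])

    def test_bonferroni_is_monotone_in_f(self, rng):
        g = np.random.default_rng(10)
        X = np.column_stack([g.standard_normal(50), np.ones(50)])
        dm = _plain_design(X, 1)
        Y = g.standard_normal((50, 300))
        fr = eb.f_contrast(eb.fit_glm(Y, dm), [0])
        order = np.argsort(fr.F)
        assert np.all(np.diff(fr.p_bonferroni[order]) <= 1e-15)
        np.testing.assert_allclose(
            fr.p_bonferroni, np.minimum(1.0, fr.p_uncorrected * 300)
        )


class TestCompareModels:
    def test_true_model_wins_three_way(self, bold_and_truth, three_way_models, basis, protocol):
        bold, truth = bold_and_truth
        mask = eb.activation_mask(bold, protocol, basis)
        rep = eb.compare_models(bold, three_way_models, basis, mode="shared", mask=mask)
        fmax = {l: rep.f_max_within(l) for l in rep.model_labels}
        assert max(fmax, key=fmax.get) == truth.ground_truth_model == "RMSF"

    def test_shared_f_not_above_separate_f(self, bold_and_truth, three_way_models, basis):
        bold, truth = bold_and_truth
        shared = eb.compare_models(bold, three_way_models, basis, mode="shared")
        separate = eb.compare_models(bold, three_way_models, basis, mode="separate")
        act = truth.active_voxels
        for label in ("TP", "RMSF"):
            f_sh = shared.f_results[label].F[act].mean()
            f_se = separate.f_results[label].F[act].mean()
            assert f_sh <= f_se * 1.05

    def test_identical_models_share_all_variance(self, tfr, bold_and_truth, basis):
        """Two copies of the same regressor set in one design leave no
        unique variance for either (the collinearity limit)."""
        bold, truth = bold_and_truth
        a = eb.build_regressors("RMSF", tfr)
        b = eb.build_regressors("MSF", tfr)  # MSF = RMSF^2, nearly collinear
        # exact duplication: relabel a copy of RMSF as uRMSF
        from eegbold.transfer import RegressorSet

        dup = RegressorSet(model_label="uRMSF", columns={"uRMSF": a.columns["RMSF"].copy()},
                           times=a.times)
        rep = eb.compare_models(bold, [a, dup], basis, mode="shared")
        act = truth.active_voxels
        sep = eb.compare_models(bold, [a], basis, mode="separate")
        assert rep.f_results["RMSF"].F[act].max() < 0.05 * sep.f_results["RMSF"].F[act].max()
        assert rep.f_results["uRMSF"].F[act].max() < 0.05 * sep.f_results["RMSF"].F[act].max()

    def test_report_bookkeeping(self, bold_and_truth, three_way_models, basis, protocol):
        bold, _ = bold_and_truth
        mask = eb.activation_mask(bold, protocol, basis)
        rep = eb.compare_models(bold, three_way_models, basis, mask=mask)
        df = rep.to_dataframe()
        assert set(df["model"]) == {"TP", "FR3", "RMSF"}
        assert set(df["location"]) == {"within", "outside"}
        for label in rep.model_labels:
            s = rep.summaries[label]
            total = s["within"]["p001_uncorrected"].n_vox + s["outside"]["p001_uncorrected"].n_vox
            assert total <= bold.n_voxels
            # FWE threshold is at least as strict as the uncorrected one here
            assert s["within"]["p05_fwe"].n_vox <= s["within"]["p001_uncorrected"].n_vox

    def test_mode_validation_and_empty_models(self, bold_and_truth, three_way_models, basis):
        bold, _ = bold_and_truth
        with pytest.raises(ValueError):
            eb.compare_models(bold, three_way_models, basis, mode="both")
        with pytest.raises(ValueError):
            eb.compare_models(bold, [], basis)


class TestActivationMask:
    def test_mask_covers_active_voxels(self, bold_and_truth, protocol, basis):
        bold, truth = bold_and_truth
        mask = eb.activation_mask(bold, protocol, basis)
        assert mask[truth.active_voxels].mean() >= 0.9

    def test_vanishing_alpha_empties_mask(self, bold_and_truth, protocol, basis):
        bold, _ = bold_and_truth
        mask = eb.activation_mask(bold, protocol, basis, alpha=0.0)
        assert mask.sum() == 0

    def test_noise_only_false_positives_controlled(self, tfr, gfp, protocol, basis):
        params = eb.BOLDSimParams(
            coupling_gain=0.0, n_voxels=300, seed=33, ar1_coefficient=0.0,
            drift_amplitude=0.0,
        )
        bold, _ = eb.simulate_bold(tfr, gfp, protocol, params, basis)
        mask = eb.activation_mask(bold, protocol, basis, alpha=0.05)
        # family-wise control: expected false positives <= alpha per family
        assert mask.sum() <= 1
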