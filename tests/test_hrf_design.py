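"""HRF basis construction, regressor downsampling, high-pass filtering and
design-matrix bookkeeping."""

import numpy as np
import pytest

import eegbold as eb
from eegbold.design import BOLDDataset, parameter_count
from eegbold.features import TimeFrequencyPower
from eegbold.hrf import canonical_hrf_basis, convolve_downsample_series
from eegbold.transfer import RegressorSet


class TestHRFBasis:
    def test_canonical_peak_near_five_seconds(self):
        """Dense-grid oracle: the double-gamma difference peaks near 5 s."""
        dense = canonical_hrf_basis(0.001)
        peak = dense.times[np.argmax(dense.canonical)]
        assert peak == pytest.approx(5.0, abs=0.05)
        basis = canonical_hrf_basis(0.1)
        assert basis.times[np.argmax(basis.canonical)] == pytest.approx(5.0, abs=0.1)

    def test_derivatives_orthogonal_to_canonical(self):
        b = canonical_hrf_basis(0.1)
        c = b.canonical
        assert abs(c @ b.temporal_derivative) < 1e-10 * np.linalg.norm(c)
        assert abs(c @ b.dispersion_derivative) < 1e-10 * np.linalg.norm(c)

    def test_refinement_consistency(self):
        """Kernels at dt and dt/2 agree after interpolation within 1%."""
        coarse = canonical_hrf_basis(0.2)
        fine = canonical_hrf_basis(0.1)
        for kc, kf in zip(coarse.kernels, fine.kernels):
            interp = np.interp(coarse.times, fine.times, kf)
            scale = np.abs(kc).max()
            assert np.abs(interp - kc).max() < 0.01 * scale

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            canonical_hrf_basis(0.0)

    def test_undershoot_present(self):
        b = canonical_hrf_basis(0.05)
        assert b.canonical.min() < 0
        assert b.canonical.max() > 0


def _regressor(series, rate, label="RMSF", name=None):
    return RegressorSet(
        model_label=label,
        columns={name or label: np.asarray(series, float)},
        times=np.arange(len(series)) / rate,
    )


class TestConvolveDownsample:
    RATE = 20.0
    TR = 3.06

    def test_impulse_response_reproduces_hrf(self):
        basis = canonical_hrf_basis(0.05)
        n_scans = 20
        t0 = 5.0
        n = int(n_scans * self.TR * self.RATE)
        q = np.zeros(n)
        q[int(t0 * self.RATE)] = self.RATE  # unit-area impulse at t0
        out = convolve_downsample_series(q, basis.canonical, self.RATE, 0.05, self.TR, n_scans)
        t_scan = (np.arange(n_scans) + 0.5) * self.TR
        expected = np.interp(t_scan - t0, basis.times, basis.canonical, left=0.0, right=0.0)
        np.testing.assert_allclose(out, expected, atol=0.02 * np.abs(expected).max())

    def test_constant_input_centres_to_zero(self, basis):
        n_scans = 12
        n = int(n_scans * self.TR * self.RATE)
        q = _regressor(np.full(n, 3.3), self.RATE)
        X, names = eb.convolve_and_downsample(q, basis, self.TR, n_scans)
        # pre-session steady-state extension: constant in -> constant out,
        # and centering removes it exactly
        assert X.shape == (n_scans, 3)
        np.testing.assert_allclose(X, 0.0, atol=1e-9)

    def test_boxcar_matches_dense_convolution_oracle(self):
        basis = canonical_hrf_basis(1.0 / self.RATE)  # kernel on the feature grid
        n_scans = 30
        n = int(n_scans * self.TR * self.RATE)
        rng = np.random.default_rng(2)
        q = (rng.random(n) > 0.5).astype(float)
        q[0] = 0.0  # oracle below assumes a quiescent pre-session state
        out = convolve_downsample_series(
            q, basis.canonical, self.RATE, basis.dt, self.TR, n_scans
        )
        dense = np.convolve(q, basis.canonical)[:n] / self.RATE
        idx = np.round((np.arange(n_scans) + 0.5) * self.TR * self.RATE).astype(int)
        np.testing.assert_allclose(out, dense[idx], atol=1e-6)

    def test_downsampling_rate_consistency(self, basis):
        """Halving the feature rate changes scan-rate regressors < 1% RMS
        (the HRF itself is the anti-alias filter)."""
        n_scans = 40
        rng = np.random.default_rng(3)
        slow = rng.standard_normal(200).cumsum()  # smooth-ish random walk
        t_fine = np.arange(int(n_scans * self.TR * 40.0)) / 40.0
        t_half = np.arange(int(n_scans * self.TR * 20.0)) / 20.0
        t_src = np.linspace(0, n_scans * self.TR, slow.size)
        q_fine = np.interp(t_fine, t_src, slow)
        q_half = np.interp(t_half, t_src, slow)
        a = convolve_downsample_series(q_fine, basis.canonical, 40.0, basis.dt, self.TR, n_scans)
        b = convolve_downsample_series(q_half, basis.canonical, 20.0, basis.dt, self.TR, n_scans)
        rms = np.sqrt(np.mean((a - b) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(a**2))

    def test_short_regressor_rejected(self, basis):
        q = _regressor(np.ones(10), self.RATE)
        with pytest.raises(ValueError, match="short"):
            eb.convolve_and_downsample(q, basis, self.TR, 50)


class TestHighpass:
    TR = 3.06

    def test_slow_cosine_removed(self):
        # period 612 s = the slowest non-constant component of a 100-scan
        # session: far above the 128 s cutoff, hence inside the filter span
        n = 100
        t = np.arange(n) * self.TR
        slow = np.cos(2 * np.pi * t / 612.0)
        out = eb.highpass(slow, self.TR, cutoff=128.0)
        assert np.sqrt(np.mean(out**2)) < 0.01 * np.sqrt(np.mean(slow**2))

    def test_fast_cosine_preserved(self):
        """Projection oracle: a 32 s cosine lies essentially outside the
        span of the >128 s discrete cosines (residual leakage ~2%)."""
        n = 100
        t = np.arange(n) * self.TR
        fast = np.cos(2 * np.pi * t / 32.0)
        out = eb.highpass(fast, self.TR, cutoff=128.0)
        assert np.sqrt(np.mean((out - fast) ** 2)) < 0.025 * np.sqrt(np.mean(fast**2))
        # independent oracle: explicit least-squares projection residual
        from eegbold.design import dct_highpass_basis

        C = dct_highpass_basis(n, self.TR, 128.0)
        coef, *_ = np.linalg.lstsq(C, fast, rcond=None)
        np.testing.assert_allclose(out, fast - C @ coef, atol=1e-10)

    def test_dct_mode_inside_span_removed_exactly(self):
        from eegbold.design import dct_highpass_basis

        C = dct_highpass_basis(100, self.TR, 128.0)
        out = eb.highpass(C[:, 2], self.TR, cutoff=128.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_constant_removed(self):
        out = eb.highpass(np.full(50, 9.9), self.TR)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)


TABLE_ROWS = [
    (["RMSF"], 10, 90),
    (["TP"], 10, 90),
    (["FR3"], 16, 144),
    (["TP", "RMSF"], 13, 117),
    (["TP", "FR3"], 19, 171),
    (["TP", "FR3", "RMSF"], 22, 198),
    (["TP", "FR3", "RMSF", "GFP"], 25, 225),
    (["RMSF", "uRMSF"], 13, 117),
    (["RMSF", "FR5"], 25, 225),
    (["RMSF", "FR8"], 34, 306),
]


class TestDesignAssembly:
    @pytest.mark.parametrize("labels, per_session, nine_sessions", TABLE_ROWS)
    def test_parameter_bookkeeping(self, labels, per_session, nine_sessions):
        assert parameter_count(labels, 1) == per_session
        assert parameter_count(labels, 9) == nine_sessions

    @staticmethod
    def _toy_session(n_scans, seed, TR=3.06, rate=2.0):
        rng = np.random.default_rng(seed)
        n = int(n_scans * TR * rate)
        tfp = TimeFrequencyPower(
            power=rng.gamma(2.0, 1.0, (40, n)) + 1e-6,
            freqs=np.arange(1.0, 41.0),
            times=np.arange(n) / rate,
        )
        return [eb.build_regressors(l, tfp) for l in ("TP", "FR3", "RMSF")]

    def _toy_bold(self, scans_per_session, seed=0, TR=3.06):
        rng = np.random.default_rng(seed)
        total = sum(scans_per_session)
        ids = np.concatenate(
            [np.full(n, s) for s, n in enumerate(scans_per_session)]
        )
        return BOLDDataset(
            Y=rng.standard_normal((total, 4)),
            TR=TR,
            session_ids=ids,
            motion=[rng.standard_normal((n, 6)) * 0.1 for n in scans_per_session],
        )

    def test_nine_session_three_way_design_has_198_columns(self, basis):
        scans = [10] * 9
        models = [self._toy_session(10, seed=s) for s in range(9)]
        bold = self._toy_bold(scans)
        dm = eb.assemble_design(models, bold, basis)
        assert dm.n_columns == 198
        assert sum(v.size for v in dm.partition.values()) == 198 - 9 * 7
        assert dm.confound_columns.size == 63

    def test_single_session_partition_sizes(self, three_way_design):
        dm = three_way_design
        assert dm.n_columns == 22
        assert dm.partition["TP"].size == 3
        assert dm.partition["FR3"].size == 9
        assert dm.partition["RMSF"].size == 3
        assert dm.confound_columns.size == 7

    @pytest.mark.parametrize(
        "label, n_cols", [("TP", 3), ("RMSF", 3), ("GFP", 3), ("FR3", 9), ("FR5", 15), ("FR8", 24)]
    )
    def test_columns_per_model(self, label, n_cols, tfr, gfp, bold_and_truth, basis):
        bold, _ = bold_and_truth
        q = eb.build_regressors(label, tfr, gfp=gfp)
        dm = eb.assemble_design([q], bold, basis)
        assert dm.partition[label].size == n_cols

    def test_duplicate_model_labels_rejected(self, three_way_models, bold_and_truth, basis):
        bold, _ = bold_and_truth
        with pytest.raises(ValueError, match="duplicate"):
            eb.assemble_design(
                [three_way_models[0], three_way_models[0]], bold, basis
            )

    def test_motion_confounds_required(self, three_way_models, basis, bold_and_truth):
        bold, _ = bold_and_truth
        bare = BOLDDataset(Y=bold.Y, TR=bold.TR)
        with pytest.raises(ValueError, match="motion"):
            eb.assemble_design(three_way_models, bare, basis)

    def test_session_independence(self, basis):
        """Permuting session order permutes design blocks without changing
        any within-session column."""
        models = [self._toy_session(10, seed=s) for s in range(3)]
        bold = self._toy_bold([10, 10, 10], seed=1)
        dm = eb.assemble_design(models, bold, basis)
        perm = [2, 0, 1]
        bold_p = BOLDDataset(
            Y=np.concatenate([bold.Y[bold.session_ids == s] for s in perm]),
            TR=bold.TR,
            session_ids=np.concatenate([np.full(10, i) for i in range(3)]),
            motion=[bold.motion[s] for s in perm],
        )
        dm_p = eb.assemble_design([models[s] for s in perm], bold_p, basis)
        # session 2's interest block in dm equals session block 0 of dm_p
        lab = "RMSF"
        orig = dm.X[np.asarray(bold.session_ids) == 2][:, dm.partition[lab][2 * 3 : 3 * 3]]
        permuted = dm_p.X[:10][:, dm_p.partition[lab][0:3]]
        np.testing.assert_allclose(orig, permuted, atol=1e-12)
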