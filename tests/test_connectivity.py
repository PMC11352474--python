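"""Denoising chain and Fisher-z connectivity."""

import numpy as np
import pandas as pd
import pytest

from reachgap.connectivity import (
    FD_HEAD_RADIUS_MM,
    bandpass_filter,
    build_confound_matrix,
    canonical_hrf,
    compcor_components,
    compute_scan_weights,
    denoise_run,
    detect_outlier_scans,
    framewise_displacement,
    regress_confounds,
    roi_to_roi_fisherz,
    subject_connectivity,
)
from reachgap.synthetic_data import simulate_motion_params

TR = 0.8


class TestFramewiseDisplacement:
    def test_constant_motion_zero(self):
        motion = np.tile([1.0, -2.0, 0.5, 0.01, 0.0, -0.02], (50, 1))
        assert np.allclose(framewise_displacement(motion), 0.0)

    def test_single_translation_jump(self):
        motion = np.zeros((50, 6))
        motion[20:, 0] = 0.6
        fd = framewise_displacement(motion)
        assert fd[20] == pytest.approx(0.6)
        assert np.count_nonzero(fd) == 1

    def test_matches_finite_difference_oracle(self, rng):
        motion = rng.normal(size=(40, 6)) * 0.1
        fd = framewise_displacement(motion)
        for t in range(1, 40):
            oracle = sum(
                abs(motion[t, j] - motion[t - 1, j]) for j in range(3)
            ) + FD_HEAD_RADIUS_MM * sum(
                abs(motion[t, j] - motion[t - 1, j]) for j in range(3, 6)
            )
            assert fd[t] == pytest.approx(oracle, abs=1e-12)
        assert fd[0] == 0.0

    def test_wrong_shape(self):
        with pytest.raises(ValueError):
            framewise_displacement(np.zeros((10, 5)))


class TestOutlierDetection:
    def test_clean_series_no_outliers(self):
        fd = np.zeros(100)
        g = np.sin(np.linspace(0, 3, 100))
        assert detect_outlier_scans(fd, g).n_outliers == 0

    def test_single_fd_spike(self):
        fd = np.zeros(100)
        fd[30] = 0.6
        mask = detect_outlier_scans(fd, np.zeros(100))
        assert mask.n_outliers == 1
        assert mask.flags[30]

    def test_global_signal_jump(self):
        g = np.random.default_rng(0).normal(size=200) * 0.1
        g[50] += 10.0
        mask = detect_outlier_scans(np.zeros(200), g)
        assert mask.flags[50] and mask.flags[51]  # jump up then back down

    def test_union_of_single_criterion_masks(self, rng):
        fd = np.abs(rng.normal(0.3, 0.2, 300))
        g = rng.normal(size=300).cumsum()
        both = detect_outlier_scans(fd, g)
        fd_only = detect_outlier_scans(fd, np.zeros(300))
        g_only = detect_outlier_scans(np.zeros(300), g)
        assert np.array_equal(both.flags, fd_only.flags | g_only.flags)


class TestCompCor:
    def test_mean_replicated_signals_have_no_usable_components(self):
        base = np.random.default_rng(1).normal(size=100)
        signals = np.tile(base[:, None], (1, 8))
        with pytest.raises(ValueError):
            compcor_components(signals, n_components=1)

    def test_recovers_latent_factor_subspace(self, rng):
        from scipy.linalg import subspace_angles

        n = 450
        factors = rng.normal(size=(n, 2))
        loadings = rng.normal(size=(2, 20))
        loadings -= loadings.mean(axis=1, keepdims=True)  # mean-free sources
        signals = factors @ loadings + 0.05 * rng.normal(size=(n, 20))
        comps = compcor_components(signals, n_components=2)
        # components are orthogonal to the removed mean signal by
        # construction, so the attainable target is the factor span after
        # the same projection
        mean = signals.mean(axis=1, keepdims=True)
        beta = np.linalg.lstsq(mean, factors, rcond=None)[0]
        target = factors - mean @ beta
        angles = np.degrees(subspace_angles(comps, target))
        assert np.max(angles) < 5.0

    def test_components_orthogonal_to_mean_and_regressors(self, rng):
        signals = rng.normal(size=(200, 15))
        motion = rng.normal(size=(200, 6))
        comps = compcor_components(signals, 5, motion)
        mean = signals.mean(axis=1)
        assert np.all(np.abs(mean @ comps) < 1e-8 * np.linalg.norm(mean))
        for j in range(6):
            proj = np.abs(motion[:, j] @ comps)
            assert np.all(proj < 1e-8 * np.linalg.norm(motion[:, j]))
        # unit-norm, mutually orthogonal columns
        assert np.allclose(comps.T @ comps, np.eye(5), atol=1e-10)


class TestConfoundRegression:
    def test_confound_column_fully_removed(self, rng):
        conf = rng.normal(size=(80, 3))
        y = np.outer(conf[:, 1], np.ones(5)) * 2.5
        resid = regress_confounds(y, conf)
        assert np.all(np.abs(resid) < 1e-10)

    def test_residuals_orthogonal_to_confounds(self, rng):
        conf = rng.normal(size=(100, 4))
        y = rng.normal(size=(100, 7))
        resid = regress_confounds(y, conf)
        assert np.all(np.abs(conf.T @ resid) < 1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=(50, 5))
            y = rng.normal(size=(50, 3))
            resid = regress_confounds(y, x)
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            assert np.allclose(resid, y - x @ beta, atol=1e-9)

    def test_rank_deficient_warns(self, rng):
        x = rng.normal(size=(30, 2))
        x = np.hstack([x, x[:, :1]])  # duplicated column
        with pytest.warns(RuntimeWarning):
            regress_confounds(rng.normal(size=(30, 2)), x)


class TestBandpass:
    def make_sine(self, freq, n=450):
        t = np.arange(n) * TR
        return np.sin(2 * np.pi * freq * t)[:, None]

    def test_passband_sinusoid_retained(self):
        x = self.make_sine(0.05)
        y = bandpass_filter(x, TR)
        assert np.linalg.norm(y) / np.linalg.norm(x) > 0.95

    def test_stopband_sinusoid_suppressed(self):
        x = self.make_sine(0.15)
        y = bandpass_filter(x, TR)
        assert np.linalg.norm(y) / np.linalg.norm(x) < 0.05

    def test_dc_removed(self):
        x = np.full((450, 2), 7.3)
        assert np.all(np.abs(bandpass_filter(x, TR)) < 1e-10)

    def test_invalid_band(self):
        x = self.make_sine(0.05)
        with pytest.raises(ValueError):
            bandpass_filter(x, TR, 0.09, 0.008)
        with pytest.raises(ValueError):
            bandpass_filter(x, TR, 0.008, 0.7)


class TestScanWeights:
    def test_plateau_reaches_one(self):
        w = compute_scan_weights(450, TR)
        late = w[int(60 / TR):]
        assert np.allclose(late, 1.0, atol=1e-3)

    def test_first_volume_downweighted(self):
        w = compute_scan_weights(450, TR)
        assert w[0] < 1.0
        assert np.all(w >= 0)
        assert w.sum() > 0

    def test_convolution_matches_direct_summation(self):
        h = canonical_hrf(TR)
        w = compute_scan_weights(100, TR)
        for t in (0, 1, 5, 40, 99):
            direct = sum(h[k] for k in range(min(t + 1, len(h))))
            assert w[t] == pytest.approx(max(direct, 0.0), abs=1e-10)


class TestFisherZ:
    def test_closed_form_values(self, rng):
        n = 5000
        x = rng.normal(size=n)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
        z = roi_to_roi_fisherz([np.column_stack([x, y])]).z
        r = np.corrcoef(x, y)[0, 1]
        assert z[0, 1] == pytest.approx(np.arctanh(r), abs=1e-10)
        # atanh(0.5) reference point
        assert np.arctanh(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_uniform_weights_equal_plain_pearson(self, rng):
        data = rng.normal(size=(300, 6))
        z = roi_to_roi_fisherz([data], [np.ones(300)]).z
        with np.errstate(divide="ignore"):
            oracle = np.arctanh(np.corrcoef(data.T))
        iu = np.triu_indices(6, 1)
        assert np.allclose(z[iu], oracle[iu], atol=1e-10)

    def test_symmetric_with_nan_diagonal(self, rng):
        z = roi_to_roi_fisherz([rng.normal(size=(100, 5))]).z
        assert np.isnan(np.diag(z)).all()
        off = ~np.eye(5, dtype=bool)
        assert np.array_equal(z[off], z.T[off])
        assert np.isfinite(z[off]).all()

    def test_zero_variance_roi_flagged(self, rng):
        data = rng.normal(size=(50, 3))
        data[:, 1] = 4.2
        with pytest.warns(RuntimeWarning):
            z = roi_to_roi_fisherz([data]).z
        assert np.isnan(z[0, 1]) and np.isfinite(z[0, 2])

    def test_edge_list_shape(self, rng):
        from reachgap.synthetic_data import roi_labels

        conn = roi_to_roi_fisherz([rng.normal(size=(60, 8))],
                                  roi_labels=roi_labels(8))
        edges = conn.edge_list()
        assert len(edges) == 28
        assert set(edges.columns) == {"roi_a", "roi_b", "z"}


def _toy_run(rng, n=450, n_rois=5):
    values = 100 + rng.normal(size=(n, n_rois))
    motion = simulate_motion_params(n, rng)
    wm = rng.normal(size=(n, 12))
    csf = rng.normal(size=(n, 12))
    return values, motion, wm, csf


class TestDenoiseRun:
    def test_residuals_orthogonal_to_all_confounds(self, rng):
        values, motion, wm, csf = _toy_run(rng)
        res = denoise_run(values, motion, wm, csf, TR)
        resid = regress_confounds(values, res.confounds)
        assert np.all(np.abs(res.confounds.T @ resid) < 1e-8)

    def test_regression_precedes_bandpass(self, rng):
        """Frequency probe: a confound mixing in- and out-of-band power
        yields different results if filtering came first."""
        n = 450
        t = np.arange(n) * TR
        c_in = np.sin(2 * np.pi * 0.05 * t)
        c_out = np.sin(2 * np.pi * 0.2 * t)
        conf = (c_in + c_out)[:, None]
        signal = np.sin(2 * np.pi * 0.03 * t)
        y = (signal + 0.8 * c_out)[:, None]

        ours = bandpass_filter(regress_confounds(y, conf), TR)
        swapped = regress_confounds(bandpass_filter(y, TR), conf)
        # the implemented order removes part of the in-band confound too
        assert np.linalg.norm(ours - swapped) > 0.1 * np.linalg.norm(swapped)
        beta = np.linalg.lstsq(conf, y, rcond=None)[0]
        assert np.allclose(
            ours, bandpass_filter(y - conf @ beta, TR), atol=1e-10
        )

    def test_full_chain_deterministic(self, rng):
        values, motion, wm, csf = _toy_run(rng)
        a = denoise_run(values, motion, wm, csf, TR).values
        b = denoise_run(values, motion, wm, csf, TR).values
        assert np.array_equal(a, b)

    def test_outlier_volume_regressed_to_zero(self, rng):
        values, motion, wm, csf = _toy_run(rng)
        motion = motion.to_numpy()
        motion[100:, 0] += 2.0  # big jump -> volume 100 flagged
        res = denoise_run(values, motion, wm, csf, TR)
        assert res.outliers.flags[100]
        resid = regress_confounds(values, res.confounds)
        assert np.all(np.abs(resid[100]) < 1e-8)

    def test_confound_matrix_layout(self, rng):
        values, motion, wm, csf = _toy_run(rng, n=200)
        res = denoise_run(values, motion, wm, csf, TR)
        names = res.confound_names
        assert names[:2] == ["constant", "trend"]
        assert sum(n.startswith("motion_") for n in names) == 12
        assert sum(n.startswith("wm_comp") for n in names) == 5
        assert sum(n.startswith("csf_comp") for n in names) == 5
        assert "wm_mean" in names and "csf_mean" in names
        assert res.confounds.shape == (200, len(names))


def test_subject_connectivity_shapes(rng):
    runs, motions, wms, csfs = [], [], [], []
    for _ in range(2):
        v, m, w, c = _toy_run(rng, n=200, n_rois=6)
        runs.append(v)
        motions.append(m)
        wms.append(w)
        csfs.append(c)
    conn = subject_connectivity(runs, motions, wms, csfs, TR,
                                [f"r{i}" for i in range(6)])
    assert conn.z.shape == (6, 6)
    assert len(conn.edge_list()) == 15
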