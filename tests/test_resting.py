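"""Amplitude spectra, ALFF/fALFF, functional connectivity, thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fnirslab as fl

from conftest import hb_recording


class TestAmplitudeSpectrum:
    def test_constant_signal(self):
        s = fl.amplitude_spectrum(np.full(100, 5.0), 10.0)
        assert s.a0 == pytest.approx(5.0)
        assert np.abs(s.Ak).max() < 1e-12

    def test_onbin_cosine_amplitude_and_phase(self):
        fs, n = 10.0, 2000
        t = np.arange(n) / fs
        x = 3.0 * np.cos(2 * np.pi * 0.05 * t - 0.7)
        s = fl.amplitude_spectrum(x, fs)
        i = np.argmin(np.abs(s.fk - 0.05))
        assert s.Ak[i] == pytest.approx(3.0, abs=1e-9)
        assert s.phik[i] == pytest.approx(0.7, abs=1e-9)
        mask = np.ones_like(s.Ak, dtype=bool)
        mask[i] = False
        assert s.Ak[mask].max() < 1e-9

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 500), n=st.sampled_from([64, 100, 101, 256]))
    def test_parseval(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        s = fl.amplitude_spectrum(x, 10.0)
        energy = s.a0**2 + np.sum(s.Ak[:-1] ** 2) / 2 + (
            s.Ak[-1] ** 2 if n % 2 == 0 else s.Ak[-1] ** 2 / 2)
        assert energy == pytest.approx((x**2).mean(), rel=1e-6)

    def test_reconstruction_from_components(self):
        """The Fourier-series convention reconstructs the signal exactly."""
        rng = np.random.default_rng(7)
        n, fs = 50, 5.0
        x = rng.standard_normal(n)
        s = fl.amplitude_spectrum(x, fs)
        t = np.arange(n) / fs
        recon = s.a0 + sum(A * np.cos(2 * np.pi * f * t - p)
                           for A, f, p in zip(s.Ak, s.fk, s.phik))
        assert np.allclose(recon, x, atol=1e-9)


class TestAlff:
    def test_single_onbin_component(self):
        fs, n = 10.0, 2000
        t = np.arange(n) / fs
        x = 2.0 * np.cos(2 * np.pi * 0.05 * t)
        other = 0.5 * x + 0.2 * np.cos(2 * np.pi * 0.3 * t)  # distinct fALFF
        rec = hb_recording(np.column_stack([x, other]),
                           np.column_stack([-x / 3, -other / 3]), fs=fs)
        res = fl.compute_alff(rec)
        assert res.alff[0] == pytest.approx(2.0 / res.n_bins, abs=1e-9)
        assert res.falff[0] == pytest.approx(1.0, abs=1e-9)
        assert res.falff[1] < 1.0

    def test_two_channel_zscores_are_plus_minus_one(self):
        fs, n = 10.0, 2000
        t = np.arange(n) / fs
        a = np.cos(2 * np.pi * 0.05 * t)
        rec = hb_recording(np.column_stack([a, 3 * a + 0.001 * np.cos(2 * np.pi * 0.2 * t)]),
                           np.column_stack([-a / 3, -a]), fs=fs)
        res = fl.compute_alff(rec)
        # population-sd z-scores of two distinct values are exactly {-1, +1}
        assert np.allclose(sorted(res.zalff), [-1.0, 1.0], atol=1e-12)

    def test_identical_channels_rejected(self):
        fs, n = 10.0, 1000
        t = np.arange(n) / fs
        a = np.cos(2 * np.pi * 0.05 * t)
        rec = hb_recording(np.column_stack([a, a]), np.column_stack([-a, -a]), fs=fs)
        with pytest.raises(ValueError, match="sd = 0"):
            fl.compute_alff(rec)

    def test_shift_invariance_and_linear_scaling(self, sinusoid_recording):
        res = fl.compute_alff(sinusoid_recording)
        shifted = sinusoid_recording.copy()
        shifted.data += 7.5
        res_shift = fl.compute_alff(shifted)
        assert np.allclose(res_shift.alff, res.alff, atol=1e-9)
        scaled = sinusoid_recording.copy()
        scaled.data *= 3.0
        res_scaled = fl.compute_alff(scaled)
        assert np.allclose(res_scaled.alff, 3.0 * res.alff, rtol=1e-9)

    def test_falff_in_unit_interval(self, sinusoid_recording):
        res = fl.compute_alff(sinusoid_recording)
        assert np.all(res.falff >= 0.0) and np.all(res.falff <= 1.0)

    def test_z_maps_standardized(self, sinusoid_recording):
        res = fl.compute_alff(sinusoid_recording)
        for z in (res.zalff, res.zfalff):
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_band_validation(self, sinusoid_recording):
        with pytest.raises(ValueError, match="band"):
            fl.compute_alff(sinusoid_recording, band=(0.08, 0.01))


def _brute_force_pearson(series):
    n = series.shape[1]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi = series[:, i] - series[:, i].mean()
            xj = series[:, j] - series[:, j].mean()
            out[i, j] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
    return out


class TestFcMatrix:
    def test_self_and_anti_correlation(self, rng):
        x = rng.standard_normal(80)
        rec = hb_recording(np.column_stack([x, x, -x]),
                           np.column_stack([-x, -x, x]))
        cm = fl.fc_matrix(rec)
        assert cm.values[0, 0] == pytest.approx(1.0)
        assert cm.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert cm.values[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_printed_toy_fixture_matches_covariance_formula(self):
        hbo = np.array([
            [1.0, 2.0, 0.5],
            [2.0, 1.5, 1.0],
            [3.0, 3.5, 0.0],
            [4.0, 2.0, 2.0],
            [5.0, 4.0, 1.5],
        ])
        rec = hb_recording(hbo, -hbo / 3, fs=1.0)
        cm = fl.fc_matrix(rec)
        assert np.allclose(cm.values, _brute_force_pearson(hbo), atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 300), n_ch=st.integers(2, 10), n_t=st.integers(5, 50))
    def test_matches_brute_force(self, seed, n_ch, n_t):
        hbo = np.random.default_rng(seed).standard_normal((n_t, n_ch))
        rec = hb_recording(hbo, -hbo / 3)
        cm = fl.fc_matrix(rec)
        assert np.allclose(cm.values, _brute_force_pearson(hbo), atol=1e-10)

    def test_symmetry_and_unit_diagonal(self, rng):
        hbo = rng.standard_normal((60, 6))
        cm = fl.fc_matrix(hb_recording(hbo, -hbo / 3))
        assert np.allclose(cm.values, cm.values.T, atol=1e-12)
        assert np.allclose(np.diag(cm.values), 1.0)

    def test_roi_modes(self, rng):
        hbo = rng.standard_normal((100, 6))
        rec = hb_recording(hbo, -hbo / 3)
        cm = fl.fc_matrix(rec, mode="roi2roi", roi_sets=[[1, 2], [3, 4], [5, 6]])
        assert cm.values.shape == (3, 3)
        m1, m2 = hbo[:, :2].mean(axis=1), hbo[:, 2:4].mean(axis=1)
        expected = np.corrcoef(m1, m2)[0, 1]
        assert cm.values[0, 1] == pytest.approx(expected, abs=1e-12)
        seed_map = fl.fc_matrix(rec, mode="roi2whole", roi_sets=[[1, 2]])
        assert seed_map.values.shape == (1, 6)
        assert seed_map.values[0, 0] == pytest.approx(
            np.corrcoef(m1, hbo[:, 0])[0, 1], abs=1e-12)

    def test_zero_variance_channel_flagged(self, rng):
        hbo = rng.standard_normal((50, 3))
        hbo[:, 1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            cm = fl.fc_matrix(hb_recording(hbo, -hbo / 3))
        assert np.isnan(cm.values[1]).all()
        assert not np.isnan(cm.values[0, 2])

    def test_fisher_z(self, rng):
        hbo = rng.standard_normal((50, 3))
        r = fl.fc_matrix(hb_recording(hbo, -hbo / 3))
        z = fl.fc_matrix(hb_recording(hbo, -hbo / 3), fisher_z=True)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(z.values[off], np.arctanh(r.values[off]), atol=1e-12)


class TestThresholding:
    def _cm(self, values):
        return fl.ConnectivityMatrix(values=np.asarray(values, dtype=float),
                                     mode="wholebrain", channel_ids=[1, 2, 3, 4])

    def test_full_sparsity_keeps_everything(self, rng):
        a = rng.uniform(0.1, 0.9, (4, 4))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        out = fl.threshold_matrix(self._cm(m), "sparsity", 1.0)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(out.values[off], m[off])

    def test_half_sparsity_keeps_three_largest(self):
        m = np.zeros((4, 4))
        vals = iter([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        for i in range(4):
            for j in range(i + 1, 4):
                m[i, j] = m[j, i] = next(vals)
        out = fl.threshold_matrix(self._cm(m), "sparsity", 0.5)
        kept = out.values[np.triu_indices(4, 1)]
        assert sorted(kept[kept > 0], reverse=True) == [0.9, 0.8, 0.7]
        assert out.threshold_state == ("sparsity", 0.5, 0.5)

    def test_tie_group_kept_with_attained_sparsity(self):
        m = np.zeros((4, 4))
        vals = iter([0.9, 0.5, 0.5, 0.5, 0.2, 0.1])
        for i in range(4):
            for j in range(i + 1, 4):
                m[i, j] = m[j, i] = next(vals)
        out = fl.threshold_matrix(self._cm(m), "sparsity", 0.5)
        assert (out.values[np.triu_indices(4, 1)] > 0).sum() == 4  # ties kept
        assert out.threshold_state[2] == pytest.approx(4 / 6)

    def test_absolute_threshold(self):
        m = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]])
        cm = fl.ConnectivityMatrix(values=m, mode="wholebrain", channel_ids=[1, 2, 3])
        out = fl.threshold_matrix(cm, "absolute", 0.3)
        assert out.values[0, 1] == 0.6 and out.values[1, 2] == 0.4
        assert out.values[0, 2] == 0.0
        empty = fl.threshold_matrix(cm, "absolute", 0.99)
        assert np.all(empty.values == 0.0)

    def test_double_thresholding_rejected(self):
        cm = self._cm(np.eye(4))
        once = fl.threshold_matrix(cm, "absolute", 0.5)
        with pytest.raises(ValueError, match="already"):
            fl.threshold_matrix(once, "absolute", 0.5)

    def test_export_round_trip(self, tmp_path, rng):
        a = rng.standard_normal((5, 5))
        m = (a + a.T) / 2
        cm = fl.ConnectivityMatrix(values=m, mode="wholebrain", channel_ids=list(range(1, 6)))
        path = tmp_path / "net.txt"
        fl.export_network(cm, path)
        assert np.allclose(np.loadtxt(path), m, atol=1e-9)

    def test_asymmetric_export_rejected(self, tmp_path):
        cm = fl.ConnectivityMatrix(values=np.arange(9.0).reshape(3, 3),
                                   mode="wholebrain", channel_ids=[1, 2, 3])
        with pytest.raises(ValueError, match="symmetric"):
            fl.export_network(cm, tmp_path / "bad.txt")
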