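"""Spectral power, AEC and iCoh estimator contracts."""

import numpy as np
import pytest

from srcconn import (RoiTimeSeriesSet, aec_matrix, amplitude_envelope_correlation,
                     band_power, band_by_name, connectivity_matrices,
                     icoh_matrix, imaginary_coherence, node_strength,
                     orthogonalize)
from srcconn.connectivity import DegeneratePairError, retained_bins
from srcconn.containers import CANONICAL_BANDS, BandDefinition, \
    ConnectivityMatrix

THETA = band_by_name("theta")
ALPHA = band_by_name("alpha")


class TestBandPower:
    def test_zero_signal_zero_power(self):
        roi = RoiTimeSeriesSet(np.zeros((3, 1024)), 128.0,
                               ["a", "b", "c"])
        bp = band_power(roi, CANONICAL_BANDS[:4])
        assert (bp.values == 0).all()

    def test_pure_alpha_tone_lands_in_alpha(self):
        fs = 128.0
        t = np.arange(int(fs * 60)) / fs
        roi = RoiTimeSeriesSet(np.sin(2 * np.pi * 10 * t)[None, :], fs,
                               ["a"])
        bp = band_power(roi, CANONICAL_BANDS[:4])
        assert bp.values[0, 2] / bp.values.sum() >= 0.99

    def test_amplitude_doubling_quadruples_power(self, small_null_dataset):
        _, subs, _ = small_null_dataset
        roi = subs[0]
        double = RoiTimeSeriesSet(2 * roi.data, roi.fs, roi.labels)
        b1 = band_power(roi, (THETA, ALPHA))
        b2 = band_power(double, (THETA, ALPHA))
        np.testing.assert_allclose(b2.values, 4 * b1.values, rtol=1e-10)

    def test_line_noise_bins_excluded(self):
        freqs = np.fft.rfftfreq(1024, 1 / 512.0)
        band = band_by_name("gamma_low")
        keep = retained_bins(freqs, band)
        assert not np.any(keep & (freqs >= 48) & (freqs <= 52))
        wide = BandDefinition("wide", 40.0, 60.0)
        keepw = retained_bins(freqs, wide)
        assert keepw[(freqs >= 46) & (freqs < 48)].all()
        assert not keepw[(freqs >= 48) & (freqs <= 52)].any()
        assert keepw[(freqs > 52) & (freqs <= 60)].all()


class TestOrthogonalize:
    def test_already_orthogonal_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)
        y = rng.standard_normal(256)
        y -= (y @ x) / (x @ x) * x
        np.testing.assert_allclose(orthogonalize(x, y), y, atol=1e-12)

    def test_collinear_pair_degenerate(self):
        x = np.sin(np.linspace(0, 20, 512))
        with pytest.raises(DegeneratePairError):
            orthogonalize(x, 3 * x)

    def test_residual_is_orthogonal(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 1024))
        r = orthogonalize(x, y)
        cos = abs(r @ x) / (np.linalg.norm(r) * np.linalg.norm(x))
        assert cos < 1e-10


class TestAec:
    def test_independent_signals_low(self, coupled_pair):
        subs, _ = coupled_pair
        a = amplitude_envelope_correlation(subs[0].data[0], subs[1].data[1],
                                           THETA, 128.0)
        assert a <= 0.15

    def test_planted_coupling_recovered(self, coupled_pair):
        subs, _ = coupled_pair
        vals = [amplitude_envelope_correlation(s.data[0], s.data[1],
                                               THETA, 128.0) for s in subs]
        assert abs(np.median(vals) - 0.6) <= 0.15

    def test_scale_and_swap_invariance(self, coupled_pair):
        subs, _ = coupled_pair
        x, y = subs[0].data
        a = amplitude_envelope_correlation(x, y, THETA, 128.0)
        b = amplitude_envelope_correlation(5 * y, 0.2 * x, THETA, 128.0)
        assert abs(a - b) < 1e-10

    def test_collinear_pair_missing(self):
        x = np.random.default_rng(0).standard_normal(128 * 80)
        assert np.isnan(
            amplitude_envelope_correlation(x, 2 * x, THETA, 128.0))

    def test_matrix_matches_pairwise(self, small_null_dataset):
        _, subs, _ = small_null_dataset
        m = aec_matrix(subs[0], THETA)
        for i, j in [(0, 1), (3, 7), (5, 11)]:
            pair = amplitude_envelope_correlation(
                subs[0].data[i], subs[0].data[j], THETA, 128.0)
            assert abs(m.weights[i, j] - pair) < 1e-9


class TestICoh:
    def test_identical_signals_zero(self):
        x = np.random.default_rng(0).standard_normal(128 * 80)
        assert imaginary_coherence(x, x.copy(), THETA, 128.0) < 0.05

    def test_quadrature_coupling_high(self):
        fs, n = 128.0, 128 * 100
        rng = np.random.default_rng(1)
        from srcconn.simulate import bandpass_carrier, fractional_delay
        x = bandpass_carrier(rng, n, THETA, fs)
        tau = (np.pi / 2) / (2 * np.pi * THETA.center)
        y = fractional_delay(x, tau, fs) + 0.05 * rng.standard_normal(n)
        assert imaginary_coherence(x, y, THETA, fs) >= 0.8

    def test_independent_signals_low(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 128 * 600))
        assert imaginary_coherence(x, y, THETA, 128.0) <= 0.15

    def test_zero_lag_mixing_invariance(self):
        """iCoh ignores added zero-lag common signal; plain coherence not."""
        rng = np.random.default_rng(3)
        from srcconn.simulate import bandpass_carrier
        n = 128 * 300
        x, y, c = (bandpass_carrier(rng, n, THETA, 128.0) for _ in range(3))
        xm, ym = x + c, y + c

        # plain-coherence oracle (magnitude, not imaginary part)
        from scipy.signal import csd
        f, sxy = csd(xm, ym, fs=128.0, nperseg=256)
        _, sxx = csd(xm, xm, fs=128.0, nperseg=256)
        _, syy = csd(ym, ym, fs=128.0, nperseg=256)
        keep = (f >= THETA.lo) & (f <= THETA.hi)
        plain = (np.abs(sxy[keep]) /
                 np.sqrt(sxx[keep].real * syy[keep].real)).mean()
        icoh = imaginary_coherence(xm, ym, THETA, 128.0)
        assert plain >= 0.4      # zero-lag mixing inflates plain coherence
        assert icoh <= 0.15      # but not the imaginary part

    def test_matrix_matches_pairwise(self, small_null_dataset):
        _, subs, _ = small_null_dataset
        mats = icoh_matrix(subs[0], (THETA, ALPHA))
        pair = imaginary_coherence(subs[0].data[2], subs[0].data[9],
                                   ALPHA, 128.0)
        assert abs(mats[1].weights[2, 9] - pair) < 1e-10


class TestMatricesAndStrength:
    def test_full_set_symmetry_and_count(self, small_null_dataset):
        _, subs, _ = small_null_dataset
        mats = connectivity_matrices(subs[0], bands=(THETA, ALPHA))
        assert len(mats) == 4  # 2 measures x 2 bands
        for m in mats:
            iu = np.triu_indices(m.n_rois, k=1)
            assert np.isfinite(m.weights[iu]).sum() == 66  # 12 choose 2
            np.testing.assert_allclose(m.weights, m.weights.T,
                                       equal_nan=True)
            assert np.nanmin(m.weights) >= 0
            assert np.nanmax(m.weights) <= 1

    def test_constant_matrix_strength(self):
        w = np.full((5, 5), 0.3)
        m = ConnectivityMatrix("s", "AEC", THETA, w)
        np.testing.assert_allclose(node_strength(m).values, 0.3)

    def test_single_edge_strength(self):
        w = np.zeros((90, 90))
        w[3, 70] = w[70, 3] = 1.0
        m = ConnectivityMatrix("s", "iCoh", THETA, w)
        s = node_strength(m).values
        assert s[3] == pytest.approx(1 / 89)
        assert s[70] == pytest.approx(1 / 89)
        assert np.delete(s, [3, 70]).max() == 0

    def test_strength_mean_equals_matrix_mean(self, small_null_dataset):
        _, subs, _ = small_null_dataset
        m = icoh_matrix(subs[0], (THETA,))[0]
        s = node_strength(m)
        assert s.values.mean() == pytest.approx(np.nanmean(m.weights))

    def test_epochs_overlapping_invalid_samples_dropped(self,
                                                        small_null_dataset):
        _, subs, _ = small_null_dataset
        roi = subs[1]
        masked = RoiTimeSeriesSet(roi.data.copy(), roi.fs, roi.labels,
                                  valid=roi.valid.copy())
        masked.data[:, 1000:1500] = 1e6  # gross artifact
        masked.valid[1000:1500] = False
        clean = icoh_matrix(roi, (THETA,))[0].weights
        robust = icoh_matrix(masked, (THETA,))[0].weights
        # masked artifact epochs do not poison the estimate
        np.testing.assert_allclose(np.nanmean(robust),
                                   np.nanmean(clean), atol=0.02)
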