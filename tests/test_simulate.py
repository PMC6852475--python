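"""Generator contracts: determinism, planted-effect realism, artifacts."""

import numpy as np
import pytest
from scipy.signal import csd

from srcconn import (PlantedEffect, SimulationConfig, band_by_name,
                     inject_artifacts, make_leadfield, mix_to_sensors,
                     simulate_sources)
from srcconn.containers import RoiTimeSeriesSet, SensorTimeSeries
from srcconn.simulate import slow_modulator

THETA = band_by_name("theta")


class TestLeadfield:
    def test_full_rank_and_positive_columns(self):
        lf = make_leadfield(128, 90, seed=1)
        assert lf.gain.shape == (128, 90)
        assert np.linalg.matrix_rank(lf.gain) == 90
        assert (np.linalg.norm(lf.gain, axis=0) > 0).all()

    def test_deterministic_for_fixed_seed(self):
        a = make_leadfield(32, 10, seed=5).gain
        b = make_leadfield(32, 10, seed=5).gain
        np.testing.assert_array_equal(a, b)

    def test_different_seed_changes_gain(self):
        a = make_leadfield(32, 10, seed=5).gain
        b = make_leadfield(32, 10, seed=6).gain
        assert not np.array_equal(a, b)


class TestSimulateSources:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_per_group=2, n_rois=4, n_sensors=8,
                               fs=128.0, duration=40.0, n_blocks=1,
                               bands=(THETA,), seed=9)
        a, _ = simulate_sources(cfg)
        b, _ = simulate_sources(cfg)
        np.testing.assert_array_equal(a[0].data, b[0].data)

    def test_planted_envelope_correlation_realised(self, coupled_pair):
        """The generator's own modulators carry the requested correlation."""
        _, truth = coupled_pair
        realized = truth.realized["realized"].to_numpy()
        assert np.all(np.abs(realized - 0.6) < 0.1)

    def test_planted_phase_coupling_spectrum(self):
        """90-degree theta coupling: high coherence at ~pi/2 relative phase."""
        eff = PlantedEffect("phase_coherence", THETA, (0, 1), 0.0,
                            baseline=0.8, phase_lag=np.pi / 2)
        cfg = SimulationConfig(n_per_group=2, n_rois=2, n_sensors=8,
                               fs=128.0, duration=300.0, n_blocks=1,
                               bands=(THETA,), planted_effects=(eff,),
                               seed=3)
        subs, _ = simulate_sources(cfg)
        x, y = subs[0].data
        f, sxy = csd(x, y, fs=128.0, nperseg=512)
        f2, sxx = csd(x, x, fs=128.0, nperseg=512)
        _, syy = csd(y, y, fs=128.0, nperseg=512)
        k = np.argmin(np.abs(f - THETA.center))
        coh2 = np.abs(sxy[k]) ** 2 / (sxx[k].real * syy[k].real)
        assert coh2 >= 0.5
        assert abs(abs(np.angle(sxy[k])) - np.pi / 2) < 0.2

    def test_band_power_effect_scales_variance(self):
        eff = PlantedEffect("band_power", THETA, (0,), -0.5)
        cfg = SimulationConfig(n_per_group=2, n_rois=2, n_sensors=8,
                               fs=128.0, duration=120.0, n_blocks=1,
                               bands=(THETA,), planted_effects=(eff,),
                               seed=4)
        subs, truth = simulate_sources(cfg)
        ctrl = next(s for s in subs if s.subject.startswith("ctrl"))
        pat = next(s for s in subs if s.subject.startswith("pat"))
        ratio = pat.data[0].var() / ctrl.data[0].var()
        assert 0.35 < ratio < 0.65  # target 0.5

    def test_unsatisfiable_target_names_effect(self):
        with pytest.raises(ValueError, match="unsatisfiable"):
            PlantedEffect("envelope_correlation", THETA, (0, 1),
                          group_delta=0.7, baseline=0.6)

    def test_zero_lag_phase_effect_rejected(self):
        with pytest.raises(ValueError, match="invisible"):
            PlantedEffect("phase_coherence", THETA, (0, 1), 0.1,
                          baseline=0.2, phase_lag=0.0)

    def test_modulator_band_limited(self):
        rng = np.random.default_rng(0)
        m = slow_modulator(rng, 2 ** 14, 128.0, cutoff=0.1)
        spec = np.abs(np.fft.rfft(m)) ** 2
        freqs = np.fft.rfftfreq(2 ** 14, 1 / 128.0)
        assert spec[freqs > 0.11].sum() < 1e-18 * spec.sum()


class TestMixToSensors:
    def test_noiseless_limit_exact(self, small_null_dataset, toy_leadfield):
        _, subs, _ = small_null_dataset
        sens = mix_to_sensors(subs[0], toy_leadfield, snr=np.inf)
        np.testing.assert_allclose(sens.data,
                                   toy_leadfield.gain @ subs[0].data)

    def test_zero_sources_noise_variance(self, toy_leadfield):
        silent = RoiTimeSeriesSet(data=np.zeros((12, 50000)), fs=128.0,
                                  labels=[f"ROI{i:02d}" for i in range(12)])
        sens = mix_to_sensors(silent, toy_leadfield, snr=4.0, seed=0)
        assert abs(sens.data.var() - 1.0) < 0.05  # unit noise floor

    def test_snr_determinism(self, small_null_dataset, toy_leadfield):
        _, subs, _ = small_null_dataset
        a = mix_to_sensors(subs[0], toy_leadfield, snr=5.0, seed=2)
        b = mix_to_sensors(subs[0], toy_leadfield, snr=5.0, seed=2)
        np.testing.assert_array_equal(a.data, b.data)


class TestInjectArtifacts:
    @pytest.fixture()
    def sensors(self):
        rng = np.random.default_rng(8)
        return SensorTimeSeries(rng.standard_normal((8, 200 * 128)), 128.0,
                                [f"E{i}" for i in range(8)])

    def test_zero_fraction_identity(self, sensors):
        out, mask = inject_artifacts(sensors, 0.0, 20.0, seed=1)
        np.testing.assert_array_equal(out.data, sensors.data)
        assert not mask.any()

    def test_only_masked_samples_differ(self, sensors):
        out, mask = inject_artifacts(sensors, 0.1, 20.0, seed=1)
        assert (out.data[mask] != sensors.data[mask]).mean() > 0.99
        np.testing.assert_array_equal(out.data[~mask], sensors.data[~mask])

    def test_mask_coverage_near_request(self, sensors):
        _, mask = inject_artifacts(sensors, 0.1, 20.0, seed=1)
        assert abs(mask.mean() - 0.1) < 0.01

    def test_fraction_bounds(self, sensors):
        with pytest.raises(ValueError):
            inject_artifacts(sensors, 0.6, 20.0)


def test_null_config_groups_exchangeable():
    """With no planted effects a per-subject summary has AUC near 1/2."""
    from srcconn.stats import auc_statistic
    cfg = SimulationConfig(n_per_group=10, n_rois=6, n_sensors=8, fs=128.0,
                           duration=30.0, n_blocks=1, bands=(THETA,),
                           seed=13)
    subs, truth = simulate_sources(cfg)
    summary = np.array([np.abs(s.data).mean() for s in subs])
    g = np.array(truth.groups)
    auc = auc_statistic(summary[g == "control"], summary[g == "patient"])
    assert 0.15 < auc < 0.85  # ~2.7 null SDs at n = 10+10
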