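"""Self-contained verification studies for the whole pipeline.

Each function regenerates its inputs from the synthetic-data module,
executes the relevant stage(s) and returns the measured quantities as a
flat dict of floats.  They back both the acceptance test suite and
``scripts/acceptance.py``.  Problem sizes are desk-scale (see the methods
note); every source of randomness derives from the single ``seed``
argument.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from .beamform import LcmvBeamformer
from .connectivity import (aec_matrix, amplitude_envelope_correlation,
                           band_power, icoh_matrix, imaginary_coherence)
from .containers import (BandDefinition, RoiTimeSeriesSet, band_by_name)
from .nmf import EnsembleNMF, _greedy_align, select_edges, select_rank_bic
from .simulate import (PlantedEffect, SimulationConfig, make_leadfield,
                       mix_to_sensors, simulate_sources)
from .stats import (EmpiricalBayes, auc_statistic, edge_features,
                    pool_band_power)
from .clinical import spearman_partial_rho

THETA = band_by_name("theta")
BETA = band_by_name("beta")


# ---------------------------------------------------------------------------
# estimator correctness against independent oracles

def _auc_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    wins = sum(1.0 if y > x else 0.5 if y == x else 0.0
               for x in a for y in b)
    return wins / (a.size * b.size)


def _dft_power_oracle(x: np.ndarray, fs: float, band) -> float:
    """Direct-summation autospectrum summed over band bins (one epoch)."""
    n = x.size
    total = 0.0
    for k in range(n // 2 + 1):
        f = k * fs / n
        if band.lo <= f <= band.hi and not (48 <= f <= 52):
            re = sum(x[t] * np.cos(-2 * np.pi * k * t / n) for t in range(n))
            im = sum(x[t] * np.sin(-2 * np.pi * k * t / n) for t in range(n))
            total += re ** 2 + im ** 2
    return total


def _icoh_oracle(x: np.ndarray, y: np.ndarray, fs: float, band,
                 n_epochs: int) -> float:
    """Naive epoch-averaged imaginary coherence by direct summation."""
    n = x.size // n_epochs
    bins = [k for k in range(n // 2 + 1)
            if band.lo <= k * fs / n <= band.hi
            and not (48 <= k * fs / n <= 52)]

    def dft(seg, k):
        return sum(seg[t] * np.exp(-2j * np.pi * k * t / n)
                   for t in range(n))

    vals = []
    for k in bins:
        sxy, sx, sy = 0j, 0.0, 0.0
        for e in range(n_epochs):
            fx = dft(x[e * n:(e + 1) * n], k)
            fy = dft(y[e * n:(e + 1) * n], k)
            sxy += fx * np.conj(fy)
            sx += abs(fx) ** 2
            sy += abs(fy) ** 2
        vals.append(abs((sxy / n_epochs).imag)
                    / np.sqrt(sx / n_epochs * sy / n_epochs))
    return float(np.mean(vals))


def estimator_correctness(seed: int = 0) -> dict[str, float]:
    """Oracle agreement of AUC, partial Spearman, band power and iCoh."""
    rng = np.random.default_rng(seed)

    auc_err = 0.0
    for _ in range(200):
        na, nb = rng.integers(1, 13, size=2)
        a = rng.integers(0, 6, na).astype(float)  # ties likely
        b = rng.integers(0, 6, nb).astype(float)
        auc_err = max(auc_err,
                      abs(auc_statistic(a, b) - _auc_bruteforce(a, b)))

    sp_err = 0.0
    from scipy.stats import spearmanr
    for _ in range(50):
        n = int(rng.integers(8, 40))
        x, y, z = rng.normal(size=(3, n))  # continuous: tie-free
        rxy = spearmanr(x, y).statistic
        rxz = spearmanr(x, z).statistic
        ryz = spearmanr(y, z).statistic
        formula = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        sp_err = max(sp_err, abs(spearman_partial_rho(x, y, z) - formula))

    # 8-sample toys at fs = 4 Hz: one 2-s epoch covers the whole signal
    toy_band = BandDefinition("toy", 0.5, 2.0)
    bp_err = 0.0
    for _ in range(20):
        x = rng.normal(size=8)
        roi = RoiTimeSeriesSet(data=x[None, :], fs=4.0, labels=["r0"])
        ours = band_power(roi, (toy_band,), epoch_seconds=2.0,
                          taper=False).values[0, 0]
        bp_err = max(bp_err, abs(ours - _dft_power_oracle(x, 4.0, toy_band))
                     / max(ours, 1e-12))

    ic_err = 0.0
    for _ in range(10):
        x, y = rng.normal(size=(2, 80))
        ours = imaginary_coherence(x, y, toy_band, fs=4.0,
                                   epoch_seconds=2.0, taper=False)
        ic_err = max(ic_err, abs(ours - _icoh_oracle(x, y, 4.0, toy_band,
                                                     n_epochs=10)))
    return {"auc_bruteforce_max_abs_err": float(auc_err),
            "spearman_partial_formula_max_abs_err": float(sp_err),
            "band_power_oracle_max_rel_err": float(bp_err),
            "icoh_oracle_max_abs_err": float(ic_err)}


# ---------------------------------------------------------------------------
# leakage robustness

def leakage_robustness(seed: int = 0, n_pairs: int = 12,
                       duration: float = 300.0, fs: float = 128.0,
                       mix: float = 0.5) -> dict[str, float]:
    """Symmetric zero-lag mixing of independent sources vs planted
    90-degree coupling.

    Sources are stationary band-limited carriers (no slow co-modulation):
    the controlled experiment isolates what zero-lag leakage alone does to
    each estimator, without the intrinsic envelope fluctuations that any
    mixing also shares between channels.
    """
    cfg = SimulationConfig(n_per_group=n_pairs, n_rois=2, n_sensors=8,
                           fs=fs, duration=duration, n_blocks=1,
                           bands=(THETA,), seed=seed, modulator_sigma=0.0)
    subs, _ = simulate_sources(cfg)
    aec_orth, aec_raw, icoh_mixed = [], [], []
    for s in subs:
        x, y = s.data
        xm, ym = x + mix * y, y + mix * x  # pure zero-lag leakage
        aec_orth.append(amplitude_envelope_correlation(xm, ym, THETA, fs))
        aec_raw.append(amplitude_envelope_correlation(
            xm, ym, THETA, fs, leakage_correction=False))
        icoh_mixed.append(imaginary_coherence(xm, ym, THETA, fs))

    cfg2 = SimulationConfig(
        n_per_group=n_pairs, n_rois=2, n_sensors=8, fs=fs,
        duration=duration, n_blocks=1, bands=(THETA,),
        planted_effects=(PlantedEffect("phase_coherence", THETA, (0, 1),
                                       0.0, baseline=0.6,
                                       phase_lag=np.pi / 2),),
        seed=seed + 1)
    subs2, _ = simulate_sources(cfg2)
    icoh_coupled = [imaginary_coherence(s.data[0], s.data[1], THETA, fs)
                    for s in subs2]
    return {
        "aec_orthogonalized_mixed_median": float(np.median(aec_orth)),
        "aec_uncorrected_mixed_median": float(np.median(aec_raw)),
        "icoh_zero_lag_mixed_median": float(np.median(icoh_mixed)),
        "icoh_planted_quadrature_median": float(np.median(icoh_coupled)),
    }


# ---------------------------------------------------------------------------
# statistical calibration under the null

def null_calibration(seed: int = 0, n_reps: int = 20, n_per_group: int = 20,
                     n_rois: int = 90, duration: float = 60.0,
                     fs: float = 128.0, n_perm: int = 500,
                     q: float = 0.10) -> dict[str, float]:
    """Full edge pipeline on exchangeable groups: realised FDP and the
    Mann-Whitney edge-selection rate at alpha = .05."""
    fdps, sel_rates = [], []
    for rep in range(n_reps):
        cfg = SimulationConfig(n_per_group=n_per_group, n_rois=n_rois,
                               n_sensors=8, fs=fs, duration=duration,
                               n_blocks=1, bands=(THETA,),
                               seed=(seed * 1009 + rep) % 2 ** 31)
        subs, truth = simulate_sources(cfg)
        mats = [icoh_matrix(s, (THETA,))[0] for s in subs]
        groups = np.array(truth.groups)
        fm = edge_features(mats, groups)
        eb = EmpiricalBayes(q=q, n_perm=n_perm,
                            seed=(seed * 31 + rep) % 2 ** 31).fit(fm.values, groups)
        n_disc = int(eb.mask_.sum())
        fdps.append(n_disc / max(n_disc, 1) if n_disc else 0.0)
        sel = select_edges(mats, groups, alpha=0.05)
        sel_rates.append(sel.edges.shape[0] / fm.values.shape[1])
    return {"null_edge_mean_fdp": float(np.mean(fdps)),
            "null_edge_selection_rate": float(np.mean(sel_rates)),
            "n_edges": float(n_rois * (n_rois - 1) // 2)}


# ---------------------------------------------------------------------------
# planted-effect recovery

AEC_EDGES = [(0, 10), (20, 30), (40, 50), (60, 70), (5, 15), (25, 35)]
ICOH_EDGES = [(1, 11), (21, 31), (41, 51), (61, 71), (6, 16), (26, 36)]


def effect_recovery(seed: int = 0, n_per_group: int = 20,
                    duration: float = 120.0, n_blocks: int = 3,
                    fs: float = 128.0, n_perm: int = 500,
                    q: float = 0.10) -> dict[str, float]:
    """Recovery of planted AEC/iCoh/power contrasts by the EBI masks.

    Patient contrasts follow the qualitative disease pattern: envelope
    co-modulation up (+0.2 on theta edges), phase synchrony down (-0.2 on
    beta edges), spectral power down (-30% in occipital regions across
    delta..beta).
    """
    from .atlas import network_indices, roi_labels
    bands4 = tuple(band_by_name(n)
                   for n in ("delta", "theta", "alpha", "beta"))
    occ = network_indices("occipital", roi_labels())
    effects = tuple(
        [PlantedEffect("envelope_correlation", THETA, e, 0.2, baseline=0.2)
         for e in AEC_EDGES]
        + [PlantedEffect("phase_coherence", BETA, e, -0.2, baseline=0.4,
                         phase_lag=np.pi / 2) for e in ICOH_EDGES]
        + [PlantedEffect("band_power", b, (int(r),), -0.3)
           for b in bands4 for r in occ])
    cfg = SimulationConfig(n_per_group=n_per_group, n_rois=90, n_sensors=8,
                           fs=fs, duration=duration, n_blocks=n_blocks,
                           bands=bands4, planted_effects=effects, seed=seed)
    subs, truth = simulate_sources(cfg)
    groups = np.array(truth.groups)

    iu = np.triu_indices(90, k=1)
    edge_id = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(*iu))}

    aec_mats = [aec_matrix(s, THETA) for s in subs]
    fm_a = edge_features(aec_mats, groups)
    eb_a = EmpiricalBayes(q=q, n_perm=n_perm, seed=seed + 1).fit(
        fm_a.values, groups)
    hits_a = [bool(eb_a.mask_[edge_id[e]]) for e in AEC_EDGES]
    auc_a = [float(eb_a.auc_[edge_id[e]]) for e in AEC_EDGES]

    icoh_mats = [icoh_matrix(s, (BETA,))[0] for s in subs]
    fm_i = edge_features(icoh_mats, groups)
    eb_i = EmpiricalBayes(q=q, n_perm=n_perm, seed=seed + 2).fit(
        fm_i.values, groups)
    hits_i = [bool(eb_i.mask_[edge_id[e]]) for e in ICOH_EDGES]
    auc_i = [float(eb_i.auc_[edge_id[e]]) for e in ICOH_EDGES]

    powers = [band_power(s, bands4) for s in subs]
    fm_p = pool_band_power(powers, groups)
    eb_p = EmpiricalBayes(q=q, n_perm=n_perm, seed=seed + 3).fit(
        fm_p.values, groups)
    planted_p = [bi * 90 + int(r) for bi in range(len(bands4)) for r in occ]
    hits_p = [bool(eb_p.mask_[k]) for k in planted_p]
    auc_p = [float(eb_p.auc_[k]) for k in planted_p]

    n_hits = sum(hits_a) + sum(hits_i) + sum(hits_p)
    n_planted = len(hits_a) + len(hits_i) + len(hits_p)
    signs_ok = (np.mean(auc_a) > 0.5 and np.mean(auc_i) < 0.5
                and np.mean(auc_p) < 0.5)
    return {"planted_recovery_fraction": n_hits / n_planted,
            "aec_recovery_fraction": float(np.mean(hits_a)),
            "icoh_recovery_fraction": float(np.mean(hits_i)),
            "power_recovery_fraction": float(np.mean(hits_p)),
            "mean_planted_aec_auc": float(np.mean(auc_a)),
            "mean_planted_icoh_auc": float(np.mean(auc_i)),
            "mean_planted_power_auc": float(np.mean(auc_p)),
            "contrast_sign_pattern_match": float(signs_ok)}


# ---------------------------------------------------------------------------
# NMF module recovery

MODULE_A = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11)]
MODULE_B = [(15, 16), (17, 18), (19, 20), (21, 22), (23, 24), (25, 26)]


def _module_dataset(seed: int, n_per_group: int = 20, n_rois: int = 30,
                    duration: float = 120.0, n_blocks: int = 3,
                    fs: float = 128.0):
    """Two opposing planted theta phase-coupling modules.

    Module A synchronises only in patients, module B only in controls, so
    the discriminant-edge iCoh matrix carries a genuine additive
    two-module structure over a near-zero background.
    """
    effects = tuple(
        [PlantedEffect("phase_coherence", THETA, e, 0.5, baseline=0.0,
                       phase_lag=np.pi / 2) for e in MODULE_A]
        + [PlantedEffect("phase_coherence", THETA, e, -0.5, baseline=0.5,
                         phase_lag=np.pi / 2) for e in MODULE_B])
    cfg = SimulationConfig(n_per_group=n_per_group, n_rois=n_rois,
                           n_sensors=8, fs=fs, duration=duration,
                           n_blocks=n_blocks, bands=(THETA,),
                           planted_effects=effects, seed=seed)
    subs, truth = simulate_sources(cfg)
    mats = [icoh_matrix(s, (THETA,))[0] for s in subs]
    return mats, np.array(truth.groups)


def nmf_module_recovery(seed: int = 0, n_bic_seeds: int = 10,
                        n_resamples: int = 30, n_restarts: int = 10,
                        ) -> dict[str, float]:
    """Recovery of two planted edge modules, BIC rank rate, H stability.

    Module mass is measured on the [0, 1]-normalised module-map scores:
    share of a recovered module's total score carried by its planted edge
    set (best one-to-one assignment).
    """
    from .nmf import module_map

    mats, groups = _module_dataset(seed)
    sel = select_edges(mats, groups, alpha=0.05)
    sel_set = {tuple(e) for e in sel.edges}
    edge_pos = {tuple(e): k for k, e in enumerate(map(tuple, sel.edges))}

    bic_hits = 0
    for s in range(n_bic_seeds):
        k, _ = select_rank_bic(sel.v, [1, 2, 3], n_restarts=n_restarts,
                               seed=(seed * 101 + s) % 2 ** 31)
        bic_hits += (k == 2)

    models = [EnsembleNMF(k=2, n_resamples=n_resamples,
                          n_restarts=n_restarts,
                          seed=(seed * 7 + r) % 2 ** 31).fit(sel.v, groups)
              for r in (1, 2)]
    h1, h2 = models[0].H_, models[1].H_
    h2a, _ = _greedy_align(h1, h2, np.zeros((1, h2.shape[0])))
    cos = [float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
           for a, b in zip(h1, h2a)]

    score_rows = [mm.scores for mm in module_map(models[0],
                                                 edges=sel.edges)]
    masses = []
    for planted in (MODULE_A, MODULE_B):
        cols = [edge_pos[e] for e in planted if e in sel_set]
        best = max(float(s[cols].sum() / s.sum()) for s in score_rows)
        masses.append(best)
    return {"nmf_module_mass_min": float(min(masses)),
            "bic_correct_rank_rate": bic_hits / n_bic_seeds,
            "ensemble_h_min_cosine": float(min(cos)),
            "n_selected_edges": float(sel.edges.shape[0])}


# ---------------------------------------------------------------------------
# beamformer contract

def beamformer_contract(seed: int = 0, n_sensors: int = 64,
                        n_rois: int = 20, fs: float = 128.0,
                        duration: float = 60.0) -> dict[str, float]:
    """Unit gain, noiseless single-source recovery and crosstalk."""
    lf = make_leadfield(n_sensors, n_rois, seed=seed)
    cfg = SimulationConfig(n_per_group=2, n_rois=n_rois, n_sensors=n_sensors,
                           fs=fs, duration=duration, n_blocks=1,
                           bands=(THETA,), seed=seed + 1)
    subs, _ = simulate_sources(cfg)
    labels = subs[0].labels
    n = subs[0].n_samples

    single = RoiTimeSeriesSet(
        data=np.vstack([subs[0].data[:1], np.zeros((n_rois - 1, n))]),
        fs=fs, labels=labels)
    sens1 = mix_to_sensors(single, lf, snr=np.inf)
    bf1 = LcmvBeamformer(lf).fit(sens1)
    gain_err = float(np.abs(
        np.einsum("rs,sr->r", bf1.weights_, lf.gain) - 1).max())
    rec1 = bf1.transform(sens1)
    corr_single = abs(float(np.corrcoef(rec1.data[0], single.data[0])[0, 1]))

    # two uncorrelated sources at the most distant ROI pair
    d = np.linalg.norm(lf.roi_positions[:, None] - lf.roi_positions[None],
                       axis=2)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    two = np.zeros((n_rois, n))
    two[i], two[j] = subs[0].data[0], subs[1].data[1]
    sens2 = mix_to_sensors(RoiTimeSeriesSet(data=two, fs=fs, labels=labels),
                           lf, snr=np.inf)
    rec2 = LcmvBeamformer(lf).fit(sens2).transform(sens2)
    own = [abs(float(np.corrcoef(rec2.data[k], two[k])[0, 1]))
           for k in (i, j)]
    cross = [abs(float(np.corrcoef(rec2.data[i], two[j])[0, 1])),
             abs(float(np.corrcoef(rec2.data[j], two[i])[0, 1]))]
    return {"lcmv_unit_gain_max_abs_err": gain_err,
            "lcmv_single_source_corr": corr_single,
            "lcmv_two_source_min_own_corr": float(min(own)),
            "lcmv_crosstalk_max": float(max(cross))}


# ---------------------------------------------------------------------------
# reproducibility

def reproducibility(seed: int = 0, base_dir: str | Path = None,
                    ) -> dict[str, float]:
    """Two identical pipeline runs must produce identical checksums."""
    import tempfile

    from .pipeline import Pipeline, PipelineConfig

    def run_once(root: Path, tag: str) -> dict[str, str]:
        cfg = PipelineConfig(
            out_dir=str(root / tag), seed=seed, n_per_group=6, n_rois=10,
            n_sensors=24, fs=64.0, duration=96.0, n_blocks=1,
            sensor_snr=8.0, artifact_fraction=0.01,
            bands=[["theta", 5, 7]], bandpass=[1.0, 30.0], notch=None,
            n_perm=100, n_boot=200, n_resamples=5, n_restarts=5,
            k_candidates=[1, 2],
            planted_effects=[dict(kind="envelope_correlation", band="theta",
                                  rois=[0, 1], group_delta=0.4,
                                  baseline=0.2)])
        Pipeline(cfg).run()
        return {
            str(p.relative_to(root / tag)):
                hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted((root / tag).rglob("*.csv"))}

    with tempfile.TemporaryDirectory(dir=base_dir) as tmp:
        d1 = run_once(Path(tmp), "a")
        d2 = run_once(Path(tmp), "b")
    identical = (d1.keys() == d2.keys()
                 and all(d1[k] == d2[k] for k in d1))
    return {"rerun_outputs_identical": float(identical),
            "n_files_compared": float(len(d1))}
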