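"""Two-group synthetic EEG generator with plantable connectivity effects.

Generates source-space (ROI) signals whose statistical structure matches
what the downstream analysis assumes, with three independently controllable
group contrasts:

* **envelope_correlation** — two ROIs share a slow (<0.5 Hz) log-envelope
  modulator with a mixing coefficient solved to hit a target correlation of
  the band-limited power envelopes (what AEC measures);
* **phase_coherence** — one ROI receives a copy of the other's band-limited
  carrier delayed by a fixed phase at the band's centre frequency, producing
  nonzero-lag synchrony visible to imaginary coherence (zero lag or π would
  be invisible to it by construction);
* **band_power** — carrier amplitude scaling, i.e. a relative power change.

Each ROI and band carries an independent band-pass-filtered white-noise
carrier; bands sum to the broadband ROI signal.  A toy forward model (current
dipole in a homogeneous conducting medium, sensors on the unit sphere) mixes
sources to 128 sensors, which is what makes zero-lag leakage testable
independently of true coupling.  All randomness flows through one seed per
operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .atlas import roi_labels, roi_positions_unit_sphere
from .containers import (
    CANONICAL_BANDS,
    BandDefinition,
    RoiTimeSeriesSet,
    SensorTimeSeries,
)

CONTROL, PATIENT = "control", "patient"


@dataclass(frozen=True)
class PlantedEffect:
    """One group contrast to plant into the simulation.

    ``group_delta`` is the difference (patient minus control) in the target
    quantity: AEC envelope correlation, iCoh coupling, or relative band
    power.  ``baseline`` is the control-group target.  ``rois`` is an ROI
    pair for the connectivity kinds, a single index for band_power.
    """

    kind: str  # envelope_correlation | phase_coherence | band_power
    band: BandDefinition
    rois: tuple[int, ...]
    group_delta: float
    baseline: float = 0.0
    phase_lag: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("envelope_correlation", "phase_coherence",
                             "band_power"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        n_expected = 1 if self.kind == "band_power" else 2
        if len(self.rois) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} ROI(s)")
        if self.kind == "phase_coherence":
            if self.phase_lag is None:
                raise ValueError("phase_coherence requires phase_lag")
            if abs(np.sin(self.phase_lag)) < 1e-6:
                raise ValueError(
                    "phase_lag must not be 0 or pi: zero-lag coupling is "
                    "invisible to imaginary coherence")
        for group, target in (("control", self.baseline),
                              ("patient", self.baseline + self.group_delta)):
            if self.kind != "band_power" and not (0 <= target <= 1):
                raise ValueError(
                    f"unsatisfiable {self.kind} effect on rois {self.rois}: "
                    f"{group} target {target} outside [0, 1]")
            if self.kind == "band_power" and target <= -1:
                raise ValueError(
                    f"unsatisfiable band_power effect on roi {self.rois}: "
                    f"{group} relative power {target} <= -100%")

    def target(self, group: str) -> float:
        return self.baseline + (self.group_delta if group == PATIENT else 0.0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-group dataset.

    Defaults follow the emulated recording protocol: three 2-minute blocks
    sampled at 512 Hz on 128 channels, 90 atlas regions, six canonical
    bands.
    """

    n_per_group: int
    n_rois: int = 90
    n_sensors: int = 128
    fs: float = 512.0
    duration: float = 120.0  # seconds per block
    n_blocks: int = 3
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    planted_effects: tuple[PlantedEffect, ...] = ()
    sensor_snr: float = 5.0  # sensor-level signal/noise variance ratio
    seed: int = 0
    modulator_sigma: float = 0.75  # std of the slow log-envelope process
    modulator_cutoff: float = 0.1  # Hz; well below the 0.5 Hz envelope rate

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        hi = max(b.hi for b in self.bands)
        if self.fs <= 2 * hi:
            raise ValueError(f"fs={self.fs} must exceed twice the highest "
                             f"band edge ({hi} Hz)")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x fs must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs)) * self.n_blocks

    @property
    def subjects(self) -> list[tuple[str, str]]:
        ids = [(f"ctrl-{i:03d}", CONTROL) for i in range(self.n_per_group)]
        ids += [(f"pat-{i:03d}", PATIENT) for i in range(self.n_per_group)]
        return ids


@dataclass
class SimulationGroundTruth:
    """Planted effects and the per-subject realized coupling values."""

    effects: pd.DataFrame  # kind, band, roi_i, roi_j, baseline, delta, targets
    realized: pd.DataFrame  # subject, group, effect index, realized value
    groups: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)


@dataclass
class LeadField:
    """Toy forward model: fixed-orientation gain, unit-sphere geometry."""

    gain: np.ndarray  # sensors x rois
    sensor_positions: np.ndarray  # sensors x 3, on the unit sphere
    roi_positions: np.ndarray  # rois x 3, inside the sphere


# ---------------------------------------------------------------------------
# helpers

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _band_sos(band: BandDefinition, fs: float, order: int = 4):
    return signal.butter(order, [band.lo, band.hi], btype="bandpass",
                         fs=fs, output="sos")


def bandpass_carrier(rng: np.random.Generator, n: int, band: BandDefinition,
                     fs: float) -> np.ndarray:
    """Unit-variance band-pass-filtered white noise (zero-phase)."""
    x = signal.sosfiltfilt(_band_sos(band, fs), rng.standard_normal(n))
    return x / x.std()


def slow_modulator(rng: np.random.Generator, n: int, fs: float,
                   cutoff: float) -> np.ndarray:
    """Unit-variance Gaussian process band-limited below ``cutoff`` Hz.

    Built by random Fourier synthesis so the band limit is exact and no
    near-DC IIR filtering is needed.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    keep = (freqs > 0) & (freqs <= cutoff)
    if keep.sum() < 2:
        raise ValueError("recording too short for the modulator cutoff")
    spec = np.zeros(freqs.size, dtype=complex)
    k = int(keep.sum())
    spec[keep] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    m = np.fft.irfft(spec, n)
    return (m - m.mean()) / m.std()


def fractional_delay(x: np.ndarray, delay_seconds: float,
                     fs: float) -> np.ndarray:
    """Circularly delay a signal by an arbitrary (fractional) lag via FFT."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return np.fft.irfft(np.fft.rfft(x) *
                        np.exp(-2j * np.pi * freqs * delay_seconds), n)


# ---------------------------------------------------------------------------
# operations

def make_leadfield(n_sensors: int, n_rois: int, seed: int = 0,
                   roi_positions: np.ndarray | None = None) -> LeadField:
    """Build the toy forward model.

    Sensors sit on a Fibonacci lattice over the unit sphere.  ROI positions
    default to the packaged atlas centroids (rescaled inside the sphere)
    when ``n_rois`` is 90, otherwise to seeded random points at radius
    0.3–0.8.  Each ROI is one current dipole with a fixed, seeded
    orientation; the gain column is the homogeneous-medium dipole potential
    at the sensors, mean-referenced and normalised to unit column norm.
    """
    rng = np.random.default_rng(seed)
    sens = _fibonacci_sphere(n_sensors)
    if roi_positions is None:
        if n_rois == 90:
            roi_positions = roi_positions_unit_sphere()
        else:
            u = rng.standard_normal((n_rois, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            radii = rng.uniform(0.3, 0.8, n_rois)
            roi_positions = u * radii[:, None]
    roi_positions = np.asarray(roi_positions, dtype=float)
    if roi_positions.shape != (n_rois, 3):
        raise ValueError("roi_positions must be n_rois x 3")

    # fixed radial/tangential orientation mix per ROI, seeded
    radial = roi_positions / np.maximum(
        np.linalg.norm(roi_positions, axis=1, keepdims=True), 1e-9)
    rand = rng.standard_normal((n_rois, 3))
    tang = rand - (rand * radial).sum(axis=1, keepdims=True) * radial
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-9)
    mix = rng.uniform(0.3, 0.7, n_rois)[:, None]
    orient = mix * radial + (1 - mix) * tang
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)

    # dipole potential in a homogeneous medium: V = q.(r - r0) / |r - r0|^3
    diff = sens[None, :, :] - roi_positions[:, None, :]  # rois x sensors x 3
    dist3 = np.linalg.norm(diff, axis=2) ** 3
    gain = np.einsum("rsk,rk->sr", diff, orient) / dist3.T
    gain -= gain.mean(axis=0, keepdims=True)
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    if not np.all(np.isfinite(gain)):
        raise ValueError("non-finite leadfield entries (dipole on a sensor?)")
    if np.linalg.matrix_rank(gain) < n_rois:
        raise ValueError("leadfield construction is rank deficient")
    return LeadField(gain=gain, sensor_positions=sens,
                     roi_positions=roi_positions)


def _index_effects(effects: tuple[PlantedEffect, ...],
                   n_rois: int, bands) -> None:
    band_names = {b.name for b in bands}
    seen_env: set[tuple] = set()
    for e in effects:
        if e.band.name not in band_names:
            raise ValueError(f"effect band {e.band.name!r} not in config bands")
        if any(r < 0 or r >= n_rois for r in e.rois):
            raise ValueError(f"effect ROI out of range: {e.rois}")
        if e.kind == "envelope_correlation":
            for r in e.rois:
                key = (e.band.name, r)
                if key in seen_env:
                    raise ValueError(
                        f"ROI {r} appears in two envelope effects in band "
                        f"{e.band.name}; overlapping envelope coupling is "
                        "not supported")
                seen_env.add(key)


def simulate_sources(
        config: SimulationConfig,
) -> tuple[list[RoiTimeSeriesSet], SimulationGroundTruth]:
    """Generate per-subject ROI time series plus ground truth.

    Uncoupled ROI pairs have expected AEC and iCoh of zero; planted effects
    realise the per-group targets described in :class:`PlantedEffect`.
    """
    _index_effects(config.planted_effects, config.n_rois, config.bands)
    n = config.n_samples
    labels = (roi_labels() if config.n_rois == 90
              else [f"ROI{i:02d}" for i in range(config.n_rois)])
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(2 * config.n_per_group)

    eff_rows = []
    for idx, e in enumerate(config.planted_effects):
        eff_rows.append({
            "effect": idx, "kind": e.kind, "band": e.band.name,
            "roi_i": e.rois[0],
            "roi_j": e.rois[1] if len(e.rois) > 1 else -1,
            "baseline": e.baseline, "group_delta": e.group_delta,
            "target_control": e.target(CONTROL),
            "target_patient": e.target(PATIENT),
            "phase_lag": e.phase_lag if e.phase_lag is not None else np.nan,
        })
    effects_df = pd.DataFrame(eff_rows, columns=[
        "effect", "kind", "band", "roi_i", "roi_j", "baseline",
        "group_delta", "target_control", "target_patient", "phase_lag"])

    subjects, realized_rows = [], []
    for (sid, group), seed in zip(config.subjects, subject_seeds):
        rng = np.random.default_rng(seed)
        data = np.zeros((config.n_rois, n))
        for band in config.bands:
            # per-ROI private modulators and carriers
            carriers = np.stack([
                bandpass_carrier(rng, n, band, config.fs)
                for _ in range(config.n_rois)])
            mods = np.stack([
                slow_modulator(rng, n, config.fs, config.modulator_cutoff)
                for _ in range(config.n_rois)])

            # envelope coupling: share a slow modulator at target correlation
            for idx, e in enumerate(config.planted_effects):
                if e.kind != "envelope_correlation" or e.band.name != band.name:
                    continue
                rho = e.target(group)
                i, j = e.rois
                shared = slow_modulator(rng, n, config.fs,
                                        config.modulator_cutoff)
                a, b = np.sqrt(rho), np.sqrt(max(0.0, 1.0 - rho))
                mods[i] = a * shared + b * mods[i]
                mods[j] = a * shared + b * mods[j]
                realized_rows.append({
                    "subject": sid, "group": group, "effect": idx,
                    "realized": float(np.corrcoef(mods[i], mods[j])[0, 1])})

            env = np.exp(config.modulator_sigma * mods)
            z = carriers * env
            z /= z.std(axis=1, keepdims=True)

            # phase coupling: add a delayed copy of the source carrier
            for idx, e in enumerate(config.planted_effects):
                if e.kind != "phase_coherence" or e.band.name != band.name:
                    continue
                i, j = e.rois
                kappa = e.target(group) / abs(np.sin(e.phase_lag))
                if kappa > 1:
                    raise ValueError(
                        f"unsatisfiable phase_coherence effect on rois "
                        f"{e.rois}: required coupling {kappa:.3f} > 1")
                tau = e.phase_lag / (2 * np.pi * e.band.center)
                z[j] = (np.sqrt(1 - kappa ** 2) * z[j]
                        + kappa * fractional_delay(z[i], tau, config.fs))
                realized_rows.append({
                    "subject": sid, "group": group, "effect": idx,
                    "realized": float(kappa)})

            # band-power effects: amplitude scaling
            amp = np.ones(config.n_rois)
            for idx, e in enumerate(config.planted_effects):
                if e.kind != "band_power" or e.band.name != band.name:
                    continue
                factor = 1.0 + e.target(group)
                amp[e.rois[0]] = np.sqrt(factor)
                realized_rows.append({
                    "subject": sid, "group": group, "effect": idx,
                    "realized": float(factor)})
            data += amp[:, None] * z

        subjects.append(RoiTimeSeriesSet(data=data, fs=config.fs,
                                         labels=labels, subject=sid))

    truth = SimulationGroundTruth(
        effects=effects_df,
        realized=pd.DataFrame(realized_rows, columns=[
            "subject", "group", "effect", "realized"]),
        groups=[g for _, g in config.subjects],
        subject_ids=[s for s, _ in config.subjects])
    return subjects, truth


def mix_to_sensors(sources: RoiTimeSeriesSet, leadfield: LeadField,
                   snr: float = 5.0, seed: int = 0) -> SensorTimeSeries:
    """Project ROI sources to sensors and add spatially white noise.

    ``snr`` is the ratio of mean sensor-level signal variance to noise
    variance; ``numpy.inf`` disables noise.
    """
    n_sensors, n_rois = leadfield.gain.shape
    if sources.n_rois != n_rois:
        raise ValueError(
            f"leadfield expects {n_rois} sources, got {sources.n_rois}")
    clean = leadfield.gain @ sources.data
    if np.isinf(snr):
        data = clean
    else:
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        noise_var = clean.var(axis=1).mean() / snr
        if noise_var == 0:  # zero sources: unit-variance noise floor
            noise_var = 1.0
        data = clean + rng.standard_normal(clean.shape) * np.sqrt(noise_var)
    labels = [f"E{i + 1:03d}" for i in range(n_sensors)]
    return SensorTimeSeries(data=data, fs=sources.fs, labels=labels,
                            positions=leadfield.sensor_positions,
                            subject=sources.subject)


def inject_artifacts(
        sensors: SensorTimeSeries, fraction: float,
        amplitude_factor: float = 20.0, seed: int = 0,
        segment_seconds: float = 1.0,
) -> tuple[SensorTimeSeries, np.ndarray]:
    """Contaminate random contiguous channel segments by amplitude scaling.

    Returns the contaminated copy and the ground-truth boolean mask
    (channels x samples) of scaled entries.  ``fraction`` is the requested
    share of all (channel, sample) entries contaminated.
    """
    if not (0 <= fraction <= 0.5):
        raise ValueError("fraction must lie in [0, 0.5]")
    out = sensors.copy()
    mask = np.zeros(out.data.shape, dtype=bool)
    if fraction == 0:
        return out, mask
    rng = np.random.default_rng(seed)
    n_ch, n_s = out.data.shape
    seg = max(1, int(round(segment_seconds * out.fs)))
    target = int(round(fraction * n_ch * n_s))
    guard = 0
    while mask.sum() < target and guard < 100 * n_ch:
        ch = int(rng.integers(n_ch))
        start = int(rng.integers(max(1, n_s - seg)))
        mask[ch, start:start + seg] = True
        guard += 1
    out.data[mask] *= amplitude_factor
    return out, mask
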