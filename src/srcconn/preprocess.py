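"""Sensor-space cleaning: statistical artifact rejection, bad-channel
interpolation, band-pass/notch filtering and common-average referencing.

The artifact rejector segments the recording into fixed windows and flags
windows whose per-channel robust statistics (peak-to-peak range, variance,
line length) are outliers across windows.  This is a concrete, testable
stand-in for "statistical thresholding" rejection; window length, threshold
and the channel fraction required to reject a window all live in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import eval_legendre

from .containers import SensorTimeSeries


@dataclass
class PreprocessConfig:
    bandpass: tuple[float, float] = (1.0, 97.0)
    notch: tuple[float, float] = (49.0, 51.0)  # band-stop edges around 50 Hz
    filter_order: int = 4
    z_threshold: float = 4.0
    window_seconds: float = 1.0
    channel_fraction: float = 0.0  # reject window if MORE than this fraction
    spline_order: int = 4  # Perrin stiffness m
    spline_reg: float = 1e-5
    spline_terms: int = 50

    def validate(self, fs: float) -> None:
        lo, hi = self.bandpass
        if not (0 < lo < hi):
            raise ValueError("bandpass must satisfy 0 < lo < hi")
        if hi >= fs / 2:
            raise ValueError(
                f"fs={fs} too low for band-pass edge {hi} Hz (need fs > {2 * hi})")


@dataclass
class RejectionReport:
    """Per-window rejection decisions plus the headline percentage."""

    percent_rejected: float
    window_seconds: float
    flags: pd.DataFrame  # window, start, stop, n_flagged_channels, rejected
    channel_stats: np.ndarray = field(repr=False, default=None)


def _robust_z(stats: np.ndarray) -> np.ndarray:
    """z-score across windows (axis 0) using median and MAD."""
    med = np.median(stats, axis=0, keepdims=True)
    mad = np.median(np.abs(stats - med), axis=0, keepdims=True)
    scale = np.maximum(1.4826 * mad, 1e-12)
    return (stats - med) / scale


def reject_artifacts(
        x: SensorTimeSeries, z_threshold: float = 4.0,
        window_seconds: float = 1.0, channel_fraction: float = 0.0,
) -> tuple[SensorTimeSeries, RejectionReport]:
    """Mark artifact-contaminated windows invalid.

    Per fixed window and channel, three statistics are computed — amplitude
    range, variance and line length — and robust-z-scored across windows.
    A channel is flagged in a window if any statistic exceeds
    ``z_threshold``; the window is rejected when the flagged-channel
    fraction exceeds ``channel_fraction`` (default: any channel).
    """
    win = int(round(window_seconds * x.fs))
    n_win = x.n_samples // win
    if n_win < 2:
        raise ValueError("need at least 2 s of data for rejection statistics")
    d = x.data[:, :n_win * win].reshape(x.n_channels, n_win, win)
    # log of strictly positive statistics: amplitude artifacts act
    # multiplicatively, and slow envelope fluctuation of genuine
    # oscillations stays near-Gaussian on the log scale
    tiny = np.finfo(float).tiny
    stats = np.log(np.maximum(np.stack([
        d.max(axis=2) - d.min(axis=2),     # peak-to-peak range
        d.var(axis=2),                     # variance
        np.abs(np.diff(d, axis=2)).sum(axis=2),  # line length
    ], axis=0), tiny))  # 3 x channels x windows
    z = _robust_z(np.transpose(stats, (2, 1, 0)))  # windows x channels x 3
    flagged = (z > z_threshold).any(axis=2)  # windows x channels
    rejected = flagged.mean(axis=1) > channel_fraction
    if rejected.all():
        raise ValueError(
            "every window was rejected; review z_threshold or the data")

    out = x.copy()
    for w in np.nonzero(rejected)[0]:
        out.valid[w * win:(w + 1) * win] = False
    flags = pd.DataFrame({
        "window": np.arange(n_win),
        "start": np.arange(n_win) * win,
        "stop": (np.arange(n_win) + 1) * win,
        "n_flagged_channels": flagged.sum(axis=1),
        "rejected": rejected,
    })
    report = RejectionReport(
        percent_rejected=100.0 * rejected.mean(),
        window_seconds=window_seconds, flags=flags, channel_stats=stats)
    return out, report


# ---------------------------------------------------------------------------
# spherical-spline interpolation (Perrin-style)

def _g_matrix(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Spherical-spline kernel g(cos) as a truncated Legendre series."""
    n = np.arange(1, n_terms + 1)
    coef = (2 * n + 1) / (n ** m * (n + 1.0) ** m)
    c = np.clip(cosang, -1.0, 1.0)
    # eval_legendre broadcasts over the last axis
    pn = eval_legendre(n, c[..., None])
    return (pn * coef).sum(axis=-1) / (4 * np.pi)


def spline_interpolation_matrix(
        good_pos: np.ndarray, bad_pos: np.ndarray, m: int = 4,
        reg: float = 1e-5, n_terms: int = 50) -> np.ndarray:
    """Matrix mapping good-channel values to bad-channel estimates.

    Perrin spherical spline on unit-sphere positions with stiffness ``m``
    and ridge regularisation ``reg`` on the kernel diagonal.  Constant
    fields are reproduced exactly via the unpenalised constant term.
    """
    g_gg = _g_matrix(good_pos @ good_pos.T, m, n_terms)
    g_bg = _g_matrix(bad_pos @ good_pos.T, m, n_terms)
    ng = good_pos.shape[0]
    a = np.zeros((ng + 1, ng + 1))
    a[:ng, :ng] = g_gg + reg * np.eye(ng)
    a[:ng, ng] = 1.0
    a[ng, :ng] = 1.0
    # solve [G+regI, 1; 1^T, 0] [w; c0] = [v; 0] for each bad channel basis
    rhs = np.zeros((ng + 1, ng))
    rhs[:ng, :] = np.eye(ng)
    sol = np.linalg.solve(a, rhs)  # (ng+1) x ng
    w, c0 = sol[:ng, :], sol[ng, :]
    return g_bg @ w + c0[None, :]


def interpolate_channels(x: SensorTimeSeries, bad_channels: list[str],
                         cfg: PreprocessConfig | None = None,
                         ) -> SensorTimeSeries:
    """Replace bad channels by spherical-spline estimates from the rest."""
    cfg = cfg or PreprocessConfig()
    if not bad_channels:
        return x.copy()
    unknown = set(bad_channels) - set(x.labels)
    if unknown:
        raise KeyError(f"bad channels not in recording: {sorted(unknown)}")
    if x.positions is None:
        raise ValueError("channel positions required for interpolation")
    bad_idx = np.array([x.labels.index(b) for b in bad_channels])
    good_idx = np.array([i for i in range(x.n_channels) if i not in set(bad_idx)])
    if good_idx.size < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    frac = bad_idx.size / x.n_channels
    if frac > 0.5:
        raise ValueError(f"{frac:.0%} of channels marked bad; refusing")
    if frac > 0.15:
        import warnings
        warnings.warn(f"interpolating {frac:.0%} of channels", stacklevel=2)
    pos = x.positions / np.linalg.norm(x.positions, axis=1, keepdims=True)
    mat = spline_interpolation_matrix(
        pos[good_idx], pos[bad_idx], m=cfg.spline_order,
        reg=cfg.spline_reg, n_terms=cfg.spline_terms)
    out = x.copy()
    out.data[bad_idx] = mat @ x.data[good_idx]
    return out


# ---------------------------------------------------------------------------
# filtering and referencing

def filter_and_reference(x: SensorTimeSeries,
                         cfg: PreprocessConfig | None = None,
                         ) -> SensorTimeSeries:
    """Zero-phase band-pass + notch filtering, then common-average reference."""
    cfg = cfg or PreprocessConfig()
    cfg.validate(x.fs)
    sos_bp = signal.butter(cfg.filter_order, cfg.bandpass, btype="bandpass",
                           fs=x.fs, output="sos")
    out = x.copy()
    out.data = signal.sosfiltfilt(sos_bp, out.data, axis=1)
    if cfg.notch is not None and cfg.notch[1] < x.fs / 2:
        sos_notch = signal.butter(cfg.filter_order, cfg.notch,
                                  btype="bandstop", fs=x.fs, output="sos")
        out.data = signal.sosfiltfilt(sos_notch, out.data, axis=1)
    out.data = common_average_reference(out.data)
    return out


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the per-sample mean across channels (idempotent)."""
    return data - data.mean(axis=0, keepdims=True)


def preprocess(x: SensorTimeSeries, cfg: PreprocessConfig | None = None,
               bad_channels: list[str] | None = None,
               ) -> tuple[SensorTimeSeries, RejectionReport]:
    """Full cleaning stage: reject -> interpolate -> filter -> re-reference."""
    cfg = cfg or PreprocessConfig()
    x, report = reject_artifacts(x, z_threshold=cfg.z_threshold,
                                 window_seconds=cfg.window_seconds,
                                 channel_fraction=cfg.channel_fraction)
    if bad_channels:
        x = interpolate_channels(x, bad_channels, cfg)
    return filter_and_reference(x, cfg), report
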