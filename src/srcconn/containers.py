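"""Core in-memory containers shared across the pipeline.

The pipeline's central currency is the :class:`RoiTimeSeriesSet` — one
source-space signal per atlas region — produced either by the LCMV
beamformer or directly by the simulator (the supported bypass for
method-level work without any sensor-space stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class SensorTimeSeries:
    """Multichannel sensor-space recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV (arbitrary units for simulated data).
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names.
    positions : ndarray, shape (n_channels, 3), optional
        Channel positions on the unit sphere (required for spherical-spline
        interpolation and the toy forward model).
    valid : ndarray of bool, shape (n_samples,), optional
        Per-sample validity mask; ``True`` means the sample is clean.
        Defaults to all-valid.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    positions: np.ndarray | None = None
    valid: np.ndarray = None  # type: ignore[assignment]
    subject: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (self.data.shape[1],):
                raise ValueError("valid mask must be one flag per sample")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.data.shape[0], 3):
                raise ValueError("positions must be channels x 3")
        if not np.all(np.isfinite(self.data[:, self.valid])):
            raise ValueError("non-finite values on valid samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "SensorTimeSeries":
        return replace(
            self,
            data=self.data.copy(),
            valid=self.valid.copy(),
            positions=None if self.positions is None else self.positions.copy(),
        )


@dataclass
class RoiTimeSeriesSet:
    """Source-space signals, one row per atlas region of interest."""

    data: np.ndarray
    fs: float
    labels: list[str]
    subject: str = ""
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be rois x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per ROI required")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (self.data.shape[1],):
                raise ValueError("valid mask must be one flag per sample")
        if not np.all(np.isfinite(self.data[:, self.valid])):
            raise ValueError("non-finite values on valid samples")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band {self.name}: need 0 < lo < hi")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


#: Canonical six bands; 48–52 Hz is excluded everywhere (power-line noise).
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 5.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
    BandDefinition("gamma_low", 31.0, 47.0),
    BandDefinition("gamma_high", 53.0, 97.0),
)

#: Frequency range never contributing to any band value (inclusive edges).
LINE_NOISE_EXCLUSION: tuple[float, float] = (48.0, 52.0)


def band_by_name(name: str, bands=CANONICAL_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI edge weights for one (measure, band, subject).

    The diagonal is not a defined quantity and is stored as NaN; missing
    (degenerate) pairs are NaN as well.  All defined weights lie in [0, 1].
    """

    subject: str
    measure: str  # "AEC" or "iCoh"
    band: BandDefinition
    weights: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        off = ~np.eye(w.shape[0], dtype=bool)
        defined = off & np.isfinite(w)
        if defined.any():
            if np.nanmin(w[defined]) < -1e-12 or np.nanmax(w[defined]) > 1 + 1e-12:
                raise ValueError("edge weights must lie in [0, 1]")
            if not np.allclose(w[defined], w.T[defined], equal_nan=True):
                raise ValueError("weights must be symmetric")
        np.fill_diagonal(w, np.nan)
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass
class BandPower:
    """Per-ROI spectral power summed over band bins, one column per band."""

    subject: str
    values: np.ndarray  # rois x bands, non-negative
    bands: tuple[BandDefinition, ...]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.bands):
            raise ValueError("values must be rois x bands")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("band power must be finite and non-negative")
        self.values = v


@dataclass
class NodeStrength:
    """Mean link weight per ROI for one connectivity matrix."""

    subject: str
    measure: str
    band: BandDefinition
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
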