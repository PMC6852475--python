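"""LCMV beamformer source reconstruction onto atlas regions.

Each ROI is represented by one equivalent dipole at its centroid.  The
spatial filter for gain vector ``l`` and sensor covariance ``C`` is the
classic minimum-variance unit-gain solution ``w = C^-1 l / (l^T C^-1 l)``;
with a 3-orientation gain the max-power orientation (dominant eigenvector
of the projected-power matrix) is chosen first.  Pre-computed ROI time
series can bypass this module entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import RoiTimeSeriesSet, SensorTimeSeries
from .simulate import LeadField


@dataclass
class Covariance:
    matrix: np.ndarray
    n_samples: int
    reg_fraction: float


def compute_covariance(x: SensorTimeSeries,
                       reg_fraction: float = 0.05) -> Covariance:
    """Sample covariance over valid samples with diagonal loading.

    Loading adds ``reg_fraction * mean(diag) * I``; with zero loading the
    data must supply at least as many valid samples as channels.
    """
    d = x.data[:, x.valid]
    n = d.shape[1]
    if n < x.n_channels and reg_fraction == 0:
        raise ValueError("fewer valid samples than channels and no "
                         "regularisation: covariance is singular")
    if n < 10 * x.n_channels:
        warnings.warn(f"only {n} valid samples for {x.n_channels} channels; "
                      "covariance estimate may be unstable", stacklevel=2)
    d = d - d.mean(axis=1, keepdims=True)
    c = (d @ d.T) / n
    c = 0.5 * (c + c.T)
    if reg_fraction:
        c = c + reg_fraction * np.mean(np.diag(c)) * np.eye(x.n_channels)
    return Covariance(matrix=c, n_samples=n, reg_fraction=reg_fraction)


def _max_power_orientation(l3: np.ndarray, cinv: np.ndarray) -> np.ndarray:
    """Max-power source orientation for a sensors x 3 gain block."""
    proj = l3.T @ cinv @ l3  # 3x3
    vals, vecs = np.linalg.eigh(proj)
    # smallest eigenvalue of L^T C^-1 L <=> dominant eigenvector of its
    # inverse, the projected-power matrix
    u = vecs[:, 0]
    return u * np.sign(u[np.argmax(np.abs(u))])


def lcmv_weights(leadfield: LeadField, cov: Covariance,
                 roi_labels: list[str] | None = None) -> np.ndarray:
    """Spatial filter matrix (rois x sensors) satisfying w^T l = 1 per ROI."""
    gain = leadfield.gain
    c = cov.matrix
    try:
        cinv = np.linalg.inv(c)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance is singular; add diagonal loading") from err
    if gain.ndim == 2:
        cols = [gain[:, i] for i in range(gain.shape[1])]
    elif gain.ndim == 3:  # sensors x rois x 3 free-orientation gain
        cols = [gain[:, i, :] @ _max_power_orientation(gain[:, i, :], cinv)
                for i in range(gain.shape[1])]
    else:
        raise ValueError("gain must be 2-D or 3-D")
    weights = np.empty((len(cols), gain.shape[0]))
    for i, l in enumerate(cols):
        cl = cinv @ l
        denom = float(l @ cl)
        if denom <= 0 or not np.isfinite(denom) or abs(denom) < 1e-300:
            name = roi_labels[i] if roi_labels else str(i)
            raise ValueError(f"numerically singular constraint for ROI {name}")
        weights[i] = cl / denom
    return weights


def extract_roi_timeseries(x: SensorTimeSeries, weights: np.ndarray,
                           labels: list[str]) -> RoiTimeSeriesSet:
    """Apply a spatial filter; the sensor validity mask propagates."""
    if weights.shape[1] != x.n_channels:
        raise ValueError("filter matrix does not match channel count")
    if weights.shape[0] != len(labels):
        raise ValueError("one label per ROI required")
    return RoiTimeSeriesSet(data=weights @ x.data, fs=x.fs, labels=labels,
                            subject=x.subject, valid=x.valid.copy())


class LcmvBeamformer(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper: fit the spatial filter, transform recordings.

    Parameters
    ----------
    leadfield : LeadField
        Forward model whose columns are ROI gain vectors.
    reg_fraction : float, default 0.05
        Diagonal loading as a fraction of mean sensor power.
    labels : list of str, optional
        ROI labels for the output (defaults to the packaged atlas when the
        leadfield has 90 sources).

    Attributes
    ----------
    covariance_ : Covariance
    weights_ : ndarray, shape (n_rois, n_sensors)
    """

    def __init__(self, leadfield: LeadField, reg_fraction: float = 0.05,
                 labels: list[str] | None = None):
        self.leadfield = leadfield
        self.reg_fraction = reg_fraction
        self.labels = labels

    def _roi_labels(self) -> list[str]:
        if self.labels is not None:
            return list(self.labels)
        n = self.leadfield.gain.shape[1]
        if n == 90:
            from .atlas import roi_labels
            return roi_labels()
        return [f"ROI{i:02d}" for i in range(n)]

    def fit(self, x: SensorTimeSeries, y=None) -> "LcmvBeamformer":
        self.covariance_ = compute_covariance(x, self.reg_fraction)
        self.weights_ = lcmv_weights(self.leadfield, self.covariance_,
                                     self._roi_labels())
        return self

    def transform(self, x: SensorTimeSeries) -> RoiTimeSeriesSet:
        if not hasattr(self, "weights_"):
            raise RuntimeError("beamformer is not fitted")
        return extract_roi_timeseries(x, self.weights_, self._roi_labels())

    def fit_transform(self, x: SensorTimeSeries, y=None) -> RoiTimeSeriesSet:
        return self.fit(x).transform(x)
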