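"""Delimited text formats for every pipeline artefact.

Sensor and ROI time series are stored as CSV with one column per channel
(header row = channel/ROI names, one row per sample) plus a JSON sidecar
(`<stem>.json`) carrying sampling rate, subject id, optional positions and
the invalid-sample intervals.  Connectivity goes out both as long edge
tables (roi_i, roi_j, measure, band, weight) and square matrix files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BandDefinition, ConnectivityMatrix, RoiTimeSeriesSet, \
    SensorTimeSeries


def _invalid_intervals(valid: np.ndarray) -> list[list[int]]:
    flips = np.flatnonzero(np.diff(np.concatenate([[True], valid, [True]])))
    return [[int(a), int(b)] for a, b in zip(flips[::2], flips[1::2])]


def _apply_intervals(n: int, intervals) -> np.ndarray:
    valid = np.ones(n, dtype=bool)
    for a, b in intervals:
        valid[a:b] = False
    return valid


def write_timeseries(ts, path) -> None:
    """Write a Sensor- or RoiTimeSeriesSet as CSV + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ts.data.T, columns=ts.labels).to_csv(path, index=False,
                                                      float_format="%.8g")
    side = {
        "fs": ts.fs,
        "subject": ts.subject,
        "kind": "sensor" if isinstance(ts, SensorTimeSeries) else "roi",
        "invalid_intervals": _invalid_intervals(ts.valid),
    }
    if getattr(ts, "positions", None) is not None:
        side["positions"] = np.round(ts.positions, 8).tolist()
    path.with_suffix(".json").write_text(json.dumps(side))


def read_timeseries(path):
    """Read a CSV + sidecar pair back into the matching container."""
    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(path.with_suffix(".json").read_text())
    data = df.to_numpy(float).T
    valid = _apply_intervals(data.shape[1], side.get("invalid_intervals", []))
    common = dict(data=data, fs=side["fs"], labels=list(df.columns),
                  subject=side.get("subject", ""), valid=valid)
    if side.get("kind") == "sensor":
        pos = side.get("positions")
        return SensorTimeSeries(positions=None if pos is None
                                else np.asarray(pos), **common)
    return RoiTimeSeriesSet(**common)


def write_matrix(m: ConnectivityMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = m.labels or [str(i) for i in range(m.n_rois)]
    pd.DataFrame(m.weights, index=labels, columns=labels).to_csv(
        path, float_format="%.8g")
    meta = {"subject": m.subject, "measure": m.measure,
            "band": [m.band.name, m.band.lo, m.band.hi]}
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    name, lo, hi = meta["band"]
    return ConnectivityMatrix(subject=meta["subject"],
                              measure=meta["measure"],
                              band=BandDefinition(name, lo, hi),
                              weights=df.to_numpy(float),
                              labels=list(df.columns))


def edge_table(matrices: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Long-format edge weights for one subject's matrices."""
    rows = []
    for m in matrices:
        iu = np.triu_indices(m.n_rois, k=1)
        rows.append(pd.DataFrame({
            "roi_i": iu[0], "roi_j": iu[1], "measure": m.measure,
            "band": m.band.name, "weight": m.weights[iu],
            "subject": m.subject}))
    return pd.concat(rows, ignore_index=True)


def write_ground_truth(truth, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    truth.effects.to_csv(path, index=False)


def write_leadfield(leadfield, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_s, n_r = leadfield.gain.shape
    pd.DataFrame(leadfield.gain,
                 index=[f"E{i + 1:03d}" for i in range(n_s)],
                 columns=[f"ROI{i:02d}" for i in range(n_r)]).to_csv(path)
    side = {"sensor_positions": leadfield.sensor_positions.tolist(),
            "roi_positions": leadfield.roi_positions.tolist()}
    path.with_suffix(".json").write_text(json.dumps(side))


def read_leadfield(path):
    from .simulate import LeadField
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    side = json.loads(path.with_suffix(".json").read_text())
    return LeadField(gain=df.to_numpy(float),
                     sensor_positions=np.asarray(side["sensor_positions"]),
                     roi_positions=np.asarray(side["roi_positions"]))
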