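"""Packaged 90-region AAL parcellation table and named network definitions.

The table covers the cortical and subcortical AAL regions (cerebellum
excluded), with hemisphere, a coarse lobe grouping
(Front / Cntr-Prtl / Occp / Tmp / Subcort) and approximate MNI centroids.
Centroids are hand-placed anatomical approximations used for the toy
spherical forward model and for region grouping only; they are not a
substitute for a subject-specific parcellation.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_ATLAS_CACHE: pd.DataFrame | None = None


def load_atlas() -> pd.DataFrame:
    """Return the packaged AAL-90 table (copy), indexed 0..89 in atlas order."""
    global _ATLAS_CACHE
    if _ATLAS_CACHE is None:
        with resources.files("srcconn.data").joinpath("aal90.csv").open() as f:
            _ATLAS_CACHE = pd.read_csv(f)
    return _ATLAS_CACHE.copy()


def roi_labels() -> list[str]:
    return load_atlas()["label"].tolist()


def roi_positions_unit_sphere(radius: float = 0.8) -> np.ndarray:
    """Atlas centroids rescaled to fit inside the unit sphere.

    The brain bounding box is mapped so the most eccentric centroid sits at
    ``radius`` (< 1, strictly inside the sensor sphere).
    """
    df = load_atlas()
    xyz = df[["centroid_x_mm", "centroid_y_mm", "centroid_z_mm"]].to_numpy(float)
    xyz = xyz - xyz.mean(axis=0)
    r = np.linalg.norm(xyz, axis=1).max()
    return xyz * (radius / r)


#: Named ROI subsets for network-level summaries.  Replaceable: any mapping
#: from network name to a list of packaged atlas labels works downstream.
def _lr(*names: str) -> list[str]:
    return [f"{n}_{h}" for n in names for h in ("L", "R")]


NETWORKS: dict[str, list[str]] = {
    "motor": _lr("Precentral", "Postcentral", "Supp_Motor_Area",
                 "Paracentral_Lobule"),
    "frontal": _lr("Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
                   "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
                   "Frontal_Inf_Orb", "Frontal_Sup_Medial", "Frontal_Med_Orb",
                   "Cingulum_Ant"),
    "frontoparietal": _lr("Frontal_Sup", "Frontal_Mid", "Frontal_Inf_Tri",
                          "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
                          "Angular", "Precuneus"),
    "frontotemporal": _lr("Frontal_Sup", "Frontal_Mid", "Frontal_Inf_Tri",
                          "Temporal_Sup", "Temporal_Mid", "Temporal_Inf",
                          "Temporal_Pole_Sup", "Temporal_Pole_Mid"),
    "occipital": _lr("Calcarine", "Cuneus", "Lingual", "Occipital_Sup",
                     "Occipital_Mid", "Occipital_Inf"),
}


def network_indices(network: str | list[str], labels: list[str]) -> np.ndarray:
    """Resolve a network name (or explicit label list) to row indices."""
    members = NETWORKS[network] if isinstance(network, str) else list(network)
    missing = [m for m in members if m not in labels]
    if missing:
        raise KeyError(f"network members not in ROI labels: {missing}")
    lookup = {lab: i for i, lab in enumerate(labels)}
    return np.array([lookup[m] for m in members], dtype=int)
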