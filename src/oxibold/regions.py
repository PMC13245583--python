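"""Region-of-interest label codes and default per-region physiology.

The phantom's label set mirrors the region battery of the aging analysis:
global gray and white matter, the medial temporal lobe with its hippocampus
and amygdala substructures, thalamus, striatum, and the frontal, parietal,
and occipital cortical lobes, plus CSF and background. Geometry is synthetic
(nested solids), but the label codes and the per-region oxygenation/perfusion
defaults are chosen so the downstream ROI statistics are exercised with the
same region structure as real segmentations would provide.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_CONSTANTS

BACKGROUND = 0
CSF = 1
GM = 2  # generic (temporal) cortical gray matter
WM = 3
MTL = 4  # medial temporal lobe (parent of hippocampus + amygdala)
HIPPOCAMPUS = 5
AMYGDALA = 6
THALAMUS = 7
STRIATUM = 8
FRONTAL = 9
PARIETAL = 10
OCCIPITAL = 11

LABEL_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    CSF: "csf",
    GM: "gm",
    WM: "wm",
    MTL: "mtl",
    HIPPOCAMPUS: "hc",
    AMYGDALA: "ag",
    THALAMUS: "thl",
    STRIATUM: "str",
    FRONTAL: "fl",
    PARIETAL: "pl",
    OCCIPITAL: "occ",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

#: the 11 regions of the cohort statistics battery, report order
REPORT_REGIONS = ["wb", "gm", "wm", "mtl", "hc", "ag", "fl", "pl", "thl", "occ", "str"]

#: composite ROI definitions (masks are unions of label codes)
COMPOSITES: dict[str, list[int]] = {
    "wb": [GM, WM, MTL, HIPPOCAMPUS, AMYGDALA, THALAMUS, STRIATUM,
           FRONTAL, PARIETAL, OCCIPITAL],
    "gm": [GM, MTL, HIPPOCAMPUS, AMYGDALA, THALAMUS, STRIATUM,
           FRONTAL, PARIETAL, OCCIPITAL],
    "wm": [WM],
    "mtl": [MTL, HIPPOCAMPUS, AMYGDALA],
    "hc": [HIPPOCAMPUS],
    "ag": [AMYGDALA],
    "thl": [THALAMUS],
    "str": [STRIATUM],
    "fl": [FRONTAL],
    "pl": [PARIETAL],
    "occ": [OCCIPITAL],
}

# Young-adult regional OEF (%) and CBF (mL/100 g/min) group means used as
# phantom defaults; R2 / DBV / susceptibility values are representative 3 T
# tissue parameters.
_YOUNG_OEF = {
    "gm": 34.9, "wm": 33.5, "mtl": 32.2, "hc": 29.1, "ag": 27.9,
    "thl": 32.5, "str": 36.2, "fl": 34.7, "pl": 38.2, "occ": 35.1,
}
_YOUNG_CBF = {
    "gm": 57.1, "wm": 30.3, "mtl": 45.5, "hc": 45.1, "ag": 39.4,
    "thl": 38.9, "str": 36.0, "fl": 57.6, "pl": 62.1, "occ": 59.1,
}

_TISSUE_BASE = {
    # label-name -> (r2 s^-1, dbv, cbvv, r2p_nh s^-1, chi_nb ppm)
    "gm": (14.5, 0.030, 0.032, 1.0, 0.010),
    "wm": (16.5, 0.020, 0.022, 1.5, -0.020),
    "mtl": (14.5, 0.028, 0.030, 1.0, 0.008),
    "hc": (14.0, 0.028, 0.030, 1.0, 0.008),
    "ag": (14.0, 0.028, 0.030, 1.0, 0.008),
    "thl": (15.5, 0.030, 0.032, 2.5, 0.030),
    "str": (16.0, 0.030, 0.032, 3.0, 0.040),
    "fl": (14.5, 0.030, 0.032, 1.0, 0.010),
    "pl": (14.5, 0.030, 0.032, 1.0, 0.010),
    "occ": (14.5, 0.030, 0.032, 1.0, 0.010),
}


def default_region_params(constants=DEFAULT_CONSTANTS) -> dict[int, dict[str, float]]:
    """Default per-label parameter table for the digital phantom.

    Yv is derived from the regional OEF via Yv = SaO2 (1 - OEF); CSF is
    modeled as slowly decaying, blood-free fluid and is excluded from the
    physiological ROI battery.
    """
    params: dict[int, dict[str, float]] = {}
    for name, (r2, dbv, cbvv, r2p_nh, chi_nb) in _TISSUE_BASE.items():
        label = NAME_TO_LABEL[name]
        oef = _YOUNG_OEF[name] / 100.0
        params[label] = {
            "yv": constants.sao2 * (1.0 - oef),
            "dbv": dbv,
            "r2": r2,
            "r2p_nh": r2p_nh,
            "chi_nb": chi_nb,
            "cbvv": cbvv,
            "cbva": 0.01,
            "cbf": _YOUNG_CBF[name],
        }
    params[CSF] = {
        "yv": constants.sao2,
        "dbv": 0.0,
        "r2": 1.5,
        "r2p_nh": 0.2,
        "chi_nb": 0.0,
        "cbvv": 0.0,
        "cbva": 0.0,
        "cbf": 0.0,
    }
    return params


def masks_from_labels(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Boolean mask per report region (composites resolved) from a label map."""
    return {
        name: np.isin(labels, COMPOSITES[name]) for name in COMPOSITES
    }
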