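"""Synthetic aging-cohort generator.

Each subject carries demographics (age, sex, hematocrit) and per-region OEF
and CBF drawn from linear-in-age means anchored at group reference values,
with Gaussian residuals. CMRO2 is never drawn independently: it is always
computed from the subject's own CBF, hematocrit, and OEF via Fick's
principle, preserving the physiological coupling between the three metrics
(a consequence: simulated CMRO2 group means follow from the OEF/CBF/Hct
draws rather than being separately configurable).

Default anchors are the young/old group means and SDs of the source study's
regional tables; default slopes are its regression coefficients (e.g. whole
brain OEF +0.150 %/year, CBF -0.207 mL/100 g/min/year). Ages are uniform
within the group ranges (23-35 and 50-87 years), hence group means match the
anchors in expectation at the range midpoints. Hemispheric values default to
exactly symmetric (laterality index 0), with configurable fractional
asymmetry offsets per region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig, RegionCohortParams
from .constants import DEFAULT_CONSTANTS, PhysicsConstants
from .physics import fick_cmro2
from .regions import REPORT_REGIONS

__all__ = [
    "default_region_cohort_params",
    "default_volume_params",
    "default_cohort_config",
    "simulate_cohort",
]

# region -> (OEF young mean, young sd, old mean, old sd,
#            CBF young mean, young sd, old mean, old sd)
_METRIC_TABLE = {
    "wb":  (34.5, 4.6, 40.2, 5.1, 48.3, 8.3, 39.5, 10.3),
    "gm":  (34.9, 4.2, 40.3, 4.7, 57.1, 10.4, 47.7, 12.9),
    "wm":  (33.5, 5.0, 39.5, 5.6, 30.3, 7.1, 28.2, 8.0),
    "mtl": (32.2, 5.1, 37.4, 5.9, 45.5, 9.2, 37.0, 10.6),
    "hc":  (29.1, 6.1, 37.2, 7.0, 45.1, 11.5, 37.0, 10.9),
    "ag":  (27.9, 6.1, 38.3, 8.6, 39.4, 8.9, 36.9, 12.0),
    "fl":  (34.7, 5.0, 38.7, 5.2, 57.6, 11.3, 44.3, 11.8),
    "pl":  (38.2, 5.5, 43.9, 5.1, 62.1, 11.3, 46.3, 13.7),
    "thl": (32.5, 7.1, 40.5, 6.4, 38.9, 8.1, 31.8, 8.4),
    "occ": (35.1, 5.3, 40.7, 6.3, 59.1, 11.1, 45.1, 14.0),
    "str": (36.2, 5.5, 42.7, 5.3, 36.0, 10.5, 28.9, 7.5),
}

# region -> (OEF slope %/year, CBF slope mL/100g/min/year)
_SLOPE_TABLE = {
    "wb":  (0.150, -0.207),
    "gm":  (0.128, -0.250),
    "wm":  (0.164, -0.051),
    "mtl": (0.141, -0.208),
    "hc":  (0.222, -0.187),
    "ag":  (0.285, -0.026),
    "fl":  (0.089, -0.327),
    "pl":  (0.149, -0.385),
    "thl": (0.211, -0.178),
    "occ": (0.162, -0.344),
    "str": (0.169, -0.159),
}

# region -> (young mean, young sd, old mean, old sd) in mL
_VOLUME_TABLE = {
    "gm":  (685.2, 72.1, 586.6, 86.3),
    "wm":  (493.9, 48.8, 457.9, 62.4),
    "hc":  (8.6, 0.9, 7.1, 1.5),
    "ag":  (3.0, 0.6, 2.7, 0.8),
    "thl": (19.9, 2.1, 17.6, 3.3),
    # CSF is not tabulated in the source; values chosen as physiologically
    # plausible for ICV ~ 1.4-1.5 L with age-related CSF expansion
    "csf": (280.0, 40.0, 340.0, 55.0),
}


def default_region_cohort_params() -> dict[str, RegionCohortParams]:
    out = {}
    for region in REPORT_REGIONS:
        oy, oys, oo, oos, cy, cys, co, cos = _METRIC_TABLE[region]
        os_, cs = _SLOPE_TABLE[region]
        out[region] = RegionCohortParams(
            oef_anchor_young=oy, oef_anchor_old=oo,
            oef_sd_young=oys, oef_sd_old=oos, oef_slope=os_,
            cbf_anchor_young=cy, cbf_anchor_old=co,
            cbf_sd_young=cys, cbf_sd_old=cos, cbf_slope=cs,
        )
    return out


def default_volume_params() -> dict[str, tuple[float, float, float, float]]:
    return dict(_VOLUME_TABLE)


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    kwargs = dict(
        regions=default_region_cohort_params(),
        volumes=default_volume_params(),
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def consistent_anchor_config(seed: int = 0, **overrides) -> CohortConfig:
    """Config variant whose old-group anchors lie exactly on the young-group
    line extended by the configured slope, so that the full-cohort regression
    estimand equals the configured slope (used for generative recovery
    checks)."""
    cfg = default_cohort_config(seed=seed, **overrides)
    gap = cfg.old_ref_age - cfg.young_ref_age
    regions = {}
    for name, rp in cfg.regions.items():
        regions[name] = RegionCohortParams(
            oef_anchor_young=rp.oef_anchor_young,
            oef_anchor_old=rp.oef_anchor_young + rp.oef_slope * gap,
            oef_sd_young=rp.oef_sd_young, oef_sd_old=rp.oef_sd_old,
            oef_slope=rp.oef_slope,
            cbf_anchor_young=rp.cbf_anchor_young,
            cbf_anchor_old=rp.cbf_anchor_young + rp.cbf_slope * gap,
            cbf_sd_young=rp.cbf_sd_young, cbf_sd_old=rp.cbf_sd_old,
            cbf_slope=rp.cbf_slope,
        )
    return CohortConfig(
        n_young=cfg.n_young, n_old=cfg.n_old,
        young_age_range=cfg.young_age_range, old_age_range=cfg.old_age_range,
        p_male=cfg.p_male, hct_mean=cfg.hct_mean, hct_sd=cfg.hct_sd,
        regions=regions, volumes=cfg.volumes,
        lr_asymmetry=cfg.lr_asymmetry, seed=cfg.seed,
    )


LATERAL_METRIC_REGIONS = ("hc", "ag")
LATERAL_VOLUME_REGIONS = ("hc", "ag", "thl")


def simulate_cohort(
    cfg: CohortConfig | None = None,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Draw one synthetic cohort; deterministic for a fixed config/seed.

    Returns one row per subject with columns: subject_id, group, age_years,
    sex (male = 1, female = 0), hct, per-region ``<region>_oef`` (%),
    ``<region>_cbf`` (mL/100 g/min), ``<region>_cmro2`` (umol/100 g/min),
    per-region volumes (mL) plus left/right splits for the lateralized
    structures and left/right metric values for hippocampus and amygdala.
    """
    if cfg is None:
        cfg = default_cohort_config()
    if not cfg.regions:
        cfg = default_cohort_config(seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    sid = 0
    for group, n, (lo, hi), ref in (
        ("young", cfg.n_young, cfg.young_age_range, cfg.young_ref_age),
        ("old", cfg.n_old, cfg.old_age_range, cfg.old_ref_age),
    ):
        for _ in range(n):
            sid += 1
            age = rng.uniform(lo, hi)
            sex = int(rng.random() < cfg.p_male)
            hct = float(np.clip(rng.normal(cfg.hct_mean, cfg.hct_sd), 0.25, 0.60))
            row = {
                "subject_id": f"sub-{sid:04d}", "group": group,
                "age_years": age, "sex": sex, "hct": hct,
            }
            for region, rp in cfg.regions.items():
                if group == "young":
                    oef_mu = rp.oef_anchor_young + rp.oef_slope * (age - ref)
                    cbf_mu = rp.cbf_anchor_young + rp.cbf_slope * (age - ref)
                    oef_sd, cbf_sd = rp.oef_sd_young, rp.cbf_sd_young
                else:
                    oef_mu = rp.oef_anchor_old + rp.oef_slope * (age - ref)
                    cbf_mu = rp.cbf_anchor_old + rp.cbf_slope * (age - ref)
                    oef_sd, cbf_sd = rp.oef_sd_old, rp.cbf_sd_old
                oef = float(np.clip(rng.normal(oef_mu, oef_sd), 1.0, 95.0))
                cbf = float(max(rng.normal(cbf_mu, cbf_sd), 1.0))
                row[f"{region}_oef"] = oef
                row[f"{region}_cbf"] = cbf
                row[f"{region}_cmro2"] = fick_cmro2(cbf, hct, oef / 100.0,
                                                    constants)
                if region in LATERAL_METRIC_REGIONS:
                    a = cfg.lr_asymmetry.get(region, 0.0)
                    for metric, v in (("oef", oef), ("cbf", cbf)):
                        right = v * (1.0 + a / 2.0)
                        left = v * (1.0 - a / 2.0)
                        row[f"{region}_right_{metric}"] = right
                        row[f"{region}_left_{metric}"] = left
                    row[f"{region}_right_cmro2"] = fick_cmro2(
                        row[f"{region}_right_cbf"], hct,
                        min(row[f"{region}_right_oef"], 95.0) / 100.0, constants)
                    row[f"{region}_left_cmro2"] = fick_cmro2(
                        row[f"{region}_left_cbf"], hct,
                        min(row[f"{region}_left_oef"], 95.0) / 100.0, constants)
            gi = 0 if group == "young" else 2
            for region, tab in cfg.volumes.items():
                vol = float(max(rng.normal(tab[gi], tab[gi + 1]), 0.1))
                row[f"{region}_volume_ml"] = vol
                if region in LATERAL_VOLUME_REGIONS:
                    a = cfg.lr_asymmetry.get(f"{region}_volume", 0.0)
                    row[f"{region}_right_volume_ml"] = vol / 2.0 * (1.0 + a / 2.0)
                    row[f"{region}_left_volume_ml"] = vol / 2.0 * (1.0 - a / 2.0)
            rows.append(row)
    return pd.DataFrame(rows)
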