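"""End-to-end pipeline driver: simulate -> priors -> constrained fit -> CMRO2
-> ROI statistics, with stage-level resumability and provenance.

Every stage writes its artifacts under the output directory; a rerun with the
same configuration and seed skips stages whose artifacts already exist and
reproduces the final report byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import regions as reg
from .cohort import default_cohort_config, simulate_cohort
from .config import AcquisitionConfig, CohortConfig, FitWeights, reject_unknown_keys
from .constants import DEFAULT_CONSTANTS, PhysicsConstants
from .inversion import cmro2_map, fit_volume
from .phantom import (
    AusfideSeries,
    make_digital_phantom,
    simulate_ausfide,
    simulate_pcasl,
    simulate_vsvsl,
)
from .priors import PriorMaps, fit_all_priors
from .stats import roi_summary, run_stats_battery
from .volio import read_volume, write_provenance, write_volume

log = logging.getLogger("oxibold")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of a full run (TOML-loadable).

    ``hct`` is the per-subject scalar hematocrit used in the constrained fit
    and Fick's principle; missing values are a validation error before any
    compute happens.
    """

    out_dir: str = "oxibold_out"
    seed: int = 0
    hct: float | None = 0.44
    phantom_shape: tuple[int, int, int] = (16, 16, 8)
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 3.0)
    ausfide_noise_sd: float = 0.0
    vsvsl_noise_sd: float = 0.0
    pcasl_noise_sd: float = 0.0
    n_young: int = 6
    n_old: int = 6
    verbosity: int = 1
    physics: PhysicsConstants = field(default_factory=PhysicsConstants)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    fit: FitWeights = field(default_factory=FitWeights)

    def __post_init__(self) -> None:
        if self.hct is None or not 0.0 < self.hct < 1.0:
            raise ValueError("hct must be provided as a fraction in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sub = {}
        if "physics" in data:
            sub["physics"] = PhysicsConstants(
                **reject_unknown_keys(PhysicsConstants, data.pop("physics")))
        if "acquisition" in data:
            sub["acquisition"] = AcquisitionConfig.from_dict(data.pop("acquisition"))
        if "fit" in data:
            sub["fit"] = FitWeights.from_dict(data.pop("fit"))
        for key in ("phantom_shape", "voxel_size_mm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**reject_unknown_keys(cls, {**data, **sub}), )

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name, out_path: Path, builder, resume: bool):
    t0 = time.time()
    if resume and out_path.exists():
        log.info("stage %s: reusing %s", name, out_path)
        return False
    try:
        builder()
    except Exception:
        log.error("stage %s failed; artifacts preserved in %s",
                  name, out_path.parent)
        raise
    log.info("stage %s: %.2f s", name, time.time() - t0)
    return True


def run_pipeline(config: PipelineConfig, resume: bool = True) -> Path:
    """Execute the full synthetic study and write the statistics report.

    Stages: phantom + acquisition simulation, prior-map estimation, the
    constrained voxelwise fit, CMRO2 mapping, ROI summaries, cohort
    simulation, and the cohort statistics battery. Returns the report
    directory. Identical config + seed reproduce identical reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_provenance(out, config.to_dict())
    acq = config.acquisition
    constants = config.physics
    vox = config.voxel_size_mm

    # ---- stage 1: phantom + simulated acquisitions --------------------------
    sim_dir = out / "sim"
    sim_dir.mkdir(exist_ok=True)
    state: dict = {}

    def build_sim():
        truth = make_digital_phantom(
            config.phantom_shape, vox, hct=config.hct, seed=config.seed,
            constants=constants)
        aus = simulate_ausfide(truth, acq, config.ausfide_noise_sd,
                               seed=config.seed + 1, constants=constants)
        vs = simulate_vsvsl(truth, acq, config.vsvsl_noise_sd,
                            seed=config.seed + 2)
        pc = simulate_pcasl(truth, acq, config.pcasl_noise_sd,
                            seed=config.seed + 3)
        state.update(truth=truth, aus=aus, vs=vs, pc=pc)
        write_volume(truth.labels, sim_dir / "labels.nii.gz", vox)
        write_volume(truth.oef(constants) * 100, sim_dir / "oef_truth.nii.gz", vox)
        np.savez_compressed(
            sim_dir / "acquisitions.npz",
            fid=aus.fid, echo=aus.echo, te_fid=aus.te_fid, te_echo=aus.te_echo,
            control=vs.control, tag=vs.tag,
            pcasl_control=pc.control, pcasl_label=pc.label, m0=pc.m0,
            labels=truth.labels,
        )

    def load_sim():
        truth = make_digital_phantom(
            config.phantom_shape, vox, hct=config.hct, seed=config.seed,
            constants=constants)
        data = np.load(sim_dir / "acquisitions.npz")
        aus = AusfideSeries(fid=data["fid"], echo=data["echo"],
                            te_fid=data["te_fid"], te_echo=data["te_echo"],
                            tr=acq.ausfide_tr, voxel_size_mm=vox)
        from .phantom import LabeledPair, PcaslSeries

        vs = LabeledPair(control=data["control"], tag=data["tag"], m0b=100.0,
                         ti=acq.vsvl_ti, blood_t1=acq.blood_t1)
        pc = PcaslSeries(control=data["pcasl_control"],
                         label=data["pcasl_label"], m0=data["m0"])
        state.update(truth=truth, aus=aus, vs=vs, pc=pc)

    if not _stage("simulate", sim_dir / "acquisitions.npz", build_sim, resume):
        load_sim()
    truth, aus, vs, pc = state["truth"], state["aus"], state["vs"], state["pc"]
    mask = truth.brain_mask
    tissue = truth.tissue_mask

    # ---- stage 2: priors -----------------------------------------------------
    pri_dir = out / "priors"
    pri_dir.mkdir(exist_ok=True)

    def build_priors():
        priors = fit_all_priors(aus, vs, pc, acq, mask, constants=constants)
        state["priors"] = priors
        for name in ("r2", "r2p", "r2star", "db0", "dchi", "cbvv", "cbf"):
            arr = getattr(priors, name)
            if arr is not None:
                write_volume(arr, pri_dir / f"{name}.nii.gz", vox)

    def load_priors():
        maps = {}
        for name in ("r2", "r2p", "r2star", "db0", "dchi", "cbvv", "cbf"):
            maps[name] = read_volume(pri_dir / f"{name}.nii.gz")[0].astype(float)
        state["priors"] = PriorMaps(**maps)

    if not _stage("fit-priors", pri_dir / "cbf.nii.gz", build_priors, resume):
        load_priors()
    priors = state["priors"]

    # ---- stage 3: constrained fit + CMRO2 ------------------------------------
    fit_dir = out / "qbold"
    fit_dir.mkdir(exist_ok=True)

    def build_fit():
        result = fit_volume(aus, priors, config.hct, acq, config.fit, tissue,
                            constants=constants)
        cmro2 = cmro2_map(result, priors.cbf, config.hct, constants)
        state["oef"] = result.oef * 100.0
        state["cmro2"] = cmro2
        write_volume(result.oef * 100.0, fit_dir / "oef_pct.nii.gz", vox)
        write_volume(result.yv, fit_dir / "yv.nii.gz", vox)
        write_volume(result.dbv, fit_dir / "dbv.nii.gz", vox)
        write_volume(cmro2, fit_dir / "cmro2.nii.gz", vox)
        (fit_dir / "summary.json").write_text(json.dumps(result.summary))

    def load_fit():
        state["oef"] = read_volume(fit_dir / "oef_pct.nii.gz")[0].astype(float)
        state["cmro2"] = read_volume(fit_dir / "cmro2.nii.gz")[0].astype(float)

    if not _stage("fit-qbold", fit_dir / "cmro2.nii.gz", build_fit, resume):
        load_fit()

    # ---- stage 4: ROI summaries ----------------------------------------------
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    import pandas as pd

    def build_roi():
        masks = reg.masks_from_labels(truth.labels)
        rows = []
        for name, m in masks.items():
            if not m.any():
                continue
            for metric, vol in (("oef", state["oef"]),
                                ("cbf", priors.cbf),
                                ("cmro2", state["cmro2"])):
                s = roi_summary(vol, m, name)
                rows.append({"region": name, "metric": metric,
                             "n_total": s.n_total, "n_kept": s.n_kept,
                             "mean": s.mean, "sd": s.sd})
        pd.DataFrame(rows).to_csv(report_dir / "roi_summary.tsv", sep="\t",
                                  index=False, float_format="%.6g")

    _stage("roi-summary", report_dir / "roi_summary.tsv", build_roi, resume)

    # ---- stage 5: cohort simulation + statistics battery ----------------------
    def build_cohort():
        cfg = default_cohort_config(seed=config.seed + 10,
                                    n_young=config.n_young, n_old=config.n_old)
        cohort = simulate_cohort(cfg, constants)
        cohort.to_csv(report_dir / "cohort.tsv", sep="\t", index=False,
                      float_format="%.8g")

    _stage("simulate-cohort", report_dir / "cohort.tsv", build_cohort, resume)

    def build_stats():
        cohort = pd.read_csv(report_dir / "cohort.tsv", sep="\t")
        tables = run_stats_battery(cohort)
        payload = {}
        for name, tdf in tables.items():
            tdf.to_csv(report_dir / f"stats_{name}.tsv", sep="\t", index=False,
                       float_format="%.8g")
            payload[name] = tdf.to_dict(orient="records")
        (report_dir / "stats.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True, default=str))

    _stage("roi-stats", report_dir / "stats.json", build_stats, resume)
    return report_dir
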