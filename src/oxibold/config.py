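"""Acquisition, fitting, and cohort configuration containers.

All configs are plain dataclasses with validation in ``__post_init__`` and a
``from_dict`` constructor that rejects unknown keys, so that a TOML config
file cannot silently misspell a parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "AcquisitionConfig",
    "FitWeights",
    "RegionCohortParams",
    "CohortConfig",
    "reject_unknown_keys",
]


def reject_unknown_keys(cls, data: Mapping[str, Any]) -> dict:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}; "
            f"known keys: {sorted(known)}"
        )
    return dict(data)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing parameters of the three simulated acquisitions (seconds).

    Defaults reproduce the in-vivo protocol: a 17-echo alternating SSFP
    FID/ECHO readout with 1.5 ms echo spacing within a 30 ms TR, a
    velocity-selective venous labeling scan with TI = 1.14 s, and a pCASL
    scan with a 2 s post-labeling delay and 6 control/tag pairs.
    """

    ausfide_first_te_fid: float = 1.6e-3
    ausfide_first_te_echo: float = 2.2e-3
    ausfide_echo_spacing: float = 1.5e-3
    ausfide_n_echoes: int = 17
    ausfide_tr: float = 30e-3
    vsvl_tr: float = 3.0
    vsvl_ts: float = 1.65
    vsvl_ti: float = 1.14
    pcasl_pld: float = 2.0
    pcasl_label_duration: float = 1.8
    pcasl_n_pairs: int = 6
    blood_t1: float = 1.65
    labeling_efficiency: float = 0.85
    partition_coefficient: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "ausfide_first_te_fid",
            "ausfide_first_te_echo",
            "ausfide_echo_spacing",
            "ausfide_tr",
            "vsvl_tr",
            "vsvl_ts",
            "vsvl_ti",
            "pcasl_pld",
            "pcasl_label_duration",
            "blood_t1",
            "labeling_efficiency",
            "partition_coefficient",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ausfide_n_echoes < 2:
            raise ValueError("ausfide_n_echoes must be >= 2")
        if self.pcasl_n_pairs < 1:
            raise ValueError("pcasl_n_pairs must be >= 1")
        if self.te_fid[-1] >= self.ausfide_tr:
            raise ValueError("last FID echo time must be < ausfide_tr")

    @property
    def te_fid(self):
        import numpy as np

        return self.ausfide_first_te_fid + self.ausfide_echo_spacing * np.arange(
            self.ausfide_n_echoes
        )

    @property
    def te_echo(self):
        import numpy as np

        return self.ausfide_first_te_echo + self.ausfide_echo_spacing * np.arange(
            self.ausfide_n_echoes
        )

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AcquisitionConfig":
        return cls(**reject_unknown_keys(cls, data))


#: physiological parameter bounds for the constrained inversion
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "yv": (0.30, 0.98),
    "dbv": (0.001, 0.10),
    "r2p_nh": (0.0, 20.0),
    "chi_nb": (-0.2, 0.2),
}


@dataclass(frozen=True)
class FitWeights:
    """Regularization weights and solver settings for the constrained fit.

    ``w`` weights the susceptibility-prior penalty (signal^2/ppm^2) and ``p``
    the R2'-prior penalty (signal^2 s^2). Either may be the string ``"auto"``,
    in which case each penalty is scaled so that, at the initialization point,
    its contribution equals the data term divided by the echo count.
    """

    w: float | str = "auto"
    p: float | str = "auto"
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    max_iter: int = 60
    tol: float = 1e-12
    multistart: int = 1
    #: outer self-consistency iterations refining the R2 prior against the
    #: data given the current parameter estimate (0 = R2 strictly fixed);
    #: corrects the small curvature bias of the monoexponential R2 prior
    refine_r2: int = 4

    def __post_init__(self) -> None:
        for name in ("w", "p"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValueError(f"{name} must be a number or 'auto'")
            elif v < 0:
                raise ValueError(f"{name} must be >= 0")
        for key, (lo, hi) in self.bounds.items():
            if not (lo < hi):
                raise ValueError(f"bounds for {key} must satisfy lower < upper")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")
        if self.refine_r2 < 0:
            raise ValueError("refine_r2 must be >= 0")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "FitWeights":
        return cls(**reject_unknown_keys(cls, data))


@dataclass(frozen=True)
class RegionCohortParams:
    """Generative parameters of one region in the aging-cohort simulator.

    Anchors are group means at the group reference age (the midpoint of the
    group's age range); OEF in percent, CBF in mL/100 g/min, slopes per year.
    SDs are the Gaussian residual scales around the linear-in-age mean.
    """

    oef_anchor_young: float
    oef_anchor_old: float
    oef_sd_young: float
    oef_sd_old: float
    oef_slope: float
    cbf_anchor_young: float
    cbf_anchor_old: float
    cbf_sd_young: float
    cbf_sd_old: float
    cbf_slope: float

    def __post_init__(self) -> None:
        for name in ("oef_sd_young", "oef_sd_old", "cbf_sd_young", "cbf_sd_old"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic aging cohort.

    Ages are drawn uniformly within each group's range; the group reference
    age used to anchor the linear-in-age regional means is the range midpoint,
    so that simulated group means match the configured anchors in expectation.
    ``lr_asymmetry`` maps a region code to a fractional right-minus-left
    offset applied to its metric values (default: perfectly symmetric
    hemispheres, laterality index 0).
    """

    n_young: int = 15
    n_old: int = 19
    young_age_range: tuple[float, float] = (23.0, 35.0)
    old_age_range: tuple[float, float] = (50.0, 87.0)
    p_male: float = 0.735
    hct_mean: float = 0.436
    hct_sd: float = 0.045
    regions: Mapping[str, RegionCohortParams] = field(default_factory=dict)
    volumes: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )  # region -> (young_mean, young_sd, old_mean, old_sd), mL
    lr_asymmetry: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 0 or self.n_old < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0.0 <= self.p_male <= 1.0:
            raise ValueError("p_male must be a probability")
        if self.hct_sd < 0:
            raise ValueError("hct_sd must be >= 0")
        y0, y1 = self.young_age_range
        o0, o1 = self.old_age_range
        if not (y0 <= y1 and o0 <= o1):
            raise ValueError("age ranges must be ordered (lo, hi)")
        if max(y0, o0) <= min(y1, o1):
            raise ValueError("group age ranges must not overlap")

    @property
    def young_ref_age(self) -> float:
        return 0.5 * (self.young_age_range[0] + self.young_age_range[1])

    @property
    def old_ref_age(self) -> float:
        return 0.5 * (self.old_age_range[0] + self.old_age_range[1])
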