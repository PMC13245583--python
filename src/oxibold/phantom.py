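"""Digital phantom construction and simulation of the three acquisitions.

No imaging data are deposited for this kind of study, so the phantom is the
ground-truth substrate for every downstream test: nested geometric solids
carry the full region label set, piecewise-constant physiological parameter
maps (with optional within-region jitter), and the three acquisitions are
simulated with the exact same closed-form models the fitters invert, plus
seeded circularly-symmetric complex Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import regions as reg
from .config import AcquisitionConfig
from .constants import DEFAULT_CONSTANTS, PhysicsConstants
from .dipole import forward_field
from .physics import VoxelState, delta_omega, qbold_signal, susceptibility_model

__all__ = [
    "PhantomTruth",
    "AusfideSeries",
    "LabeledPair",
    "PcaslSeries",
    "make_digital_phantom",
    "simulate_ausfide",
    "simulate_vsvsl",
    "simulate_pcasl",
]

PARAM_KEYS = ("yv", "dbv", "r2", "r2p_nh", "chi_nb", "cbvv", "cbva", "cbf")


@dataclass
class PhantomTruth:
    """Voxelwise ground truth: ROI labels plus physiological parameter maps."""

    labels: np.ndarray
    yv: np.ndarray
    dbv: np.ndarray
    r2: np.ndarray
    r2p_nh: np.ndarray
    chi_nb: np.ndarray
    cbvv: np.ndarray
    cbva: np.ndarray
    cbf: np.ndarray
    db0_background: np.ndarray
    hct: float = 0.44
    b0: float = 3.0
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 3.0)

    def validate(self, constants: PhysicsConstants = DEFAULT_CONSTANTS) -> None:
        for name in ("yv", "dbv", "cbvv", "cbva"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.dbv > self.cbvv + 1e-6):
            raise ValueError("DBV must not exceed CBVv")
        for name in ("r2", "r2p_nh", "cbf"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be >= 0")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")
        finite = np.isfinite(self.yv)
        if np.any((self.labels == 0) & finite & (self.yv != 0)):
            # background voxels must carry no physiology
            raise ValueError("nonzero parameters outside labeled tissue")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def tissue_mask(self) -> np.ndarray:
        """Voxels with blood-bearing tissue (labels excluding CSF/background)."""
        return self.labels >= reg.GM

    def voxel_state(self, a_f=1.0, a_e=1.0) -> VoxelState:
        return VoxelState(
            yv=self.yv,
            dbv=self.dbv,
            r2=self.r2,
            r2p_nh=self.r2p_nh,
            chi_nb=self.chi_nb,
            cbvv=self.cbvv,
            cbva=self.cbva,
            hct=self.hct,
            a_f=a_f,
            a_e=a_e,
        )

    def chi_total(self, constants: PhysicsConstants = DEFAULT_CONSTANTS) -> np.ndarray:
        """Per-voxel susceptibility (ppm) from the four-pool model; 0 outside."""
        chi = susceptibility_model(self.voxel_state(), constants)
        return np.where(self.brain_mask, chi, 0.0)

    def db0_total(self, constants: PhysicsConstants = DEFAULT_CONSTANTS) -> np.ndarray:
        """Total field offset (ppm): polynomial background plus the dipole
        field of the voxel susceptibility distribution."""
        return self.db0_background + forward_field(
            self.chi_total(constants), self.voxel_size_mm
        )

    def oef(self, constants: PhysicsConstants = DEFAULT_CONSTANTS) -> np.ndarray:
        return (constants.sao2 - self.yv) / constants.sao2


@dataclass
class AusfideSeries:
    """Complex multi-echo FID and ECHO volumes with echo-time metadata."""

    fid: np.ndarray  # complex, shape (*grid, n_echoes)
    echo: np.ndarray
    te_fid: np.ndarray
    te_echo: np.ndarray
    tr: float
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 3.0)


@dataclass
class LabeledPair:
    """Control/tag volume pair from the venous spin-labeling scan."""

    control: np.ndarray
    tag: np.ndarray
    m0b: float
    ti: float
    blood_t1: float


@dataclass
class PcaslSeries:
    """pCASL control/label pair series plus the M0 calibration volume."""

    control: np.ndarray  # shape (n_pairs, *grid)
    label: np.ndarray
    m0: np.ndarray


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

def _normalized_coords(shape):
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _box(x, y, z, xr, yr, zr):
    return (
        (x >= xr[0]) & (x < xr[1])
        & (y >= yr[0]) & (y < yr[1])
        & (z >= zr[0]) & (z < zr[1])
    )


def _build_labels(shape, wanted: set[int] | None = None) -> np.ndarray:
    """Nested synthetic geometry carrying the requested label codes.

    An outer ellipsoid is split into a CSF rind, a cortical shell partitioned
    into lobes by angular sectors, and a deep core of white matter in which
    box-shaped subcortical structures (MTL with hippocampus and amygdala,
    thalamus, striatum) are embedded. Later assignments overwrite earlier
    ones, guaranteeing disjoint labels. When ``wanted`` restricts the label
    set, absent structures are simply not carved out of their parent tissue
    (e.g. a two-region phantom is a GM shell around a WM core).
    """
    x, y, z = _normalized_coords(shape)
    r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    labels = np.zeros(shape, dtype=np.int16)

    def want(code):
        return wanted is None or code in wanted

    if want(reg.CSF):
        labels[r <= 0.95] = reg.CSF
    cortex = r <= 0.82
    labels[cortex] = reg.GM
    labels[r <= 0.58] = reg.WM

    shell = cortex & (r > 0.58)
    if want(reg.FRONTAL):
        labels[shell & (y >= 0.18)] = reg.FRONTAL
    if want(reg.OCCIPITAL):
        labels[shell & (y <= -0.18)] = reg.OCCIPITAL
    if want(reg.PARIETAL):
        labels[shell & (np.abs(y) < 0.18) & (z >= 0.1)] = reg.PARIETAL
    # remaining shell voxels keep the generic (temporal) GM code

    # subcortical boxes inside the WM core
    if want(reg.THALAMUS):
        labels[_box(x, y, z, (-0.16, 0.16), (-0.12, 0.20), (-0.16, 0.16))] = (
            reg.THALAMUS)
    if want(reg.STRIATUM):
        for sgn in (-1, 1):
            labels[
                _box(x, y, z, tuple(sorted((sgn * 0.20, sgn * 0.44))),
                     (0.02, 0.34), (-0.16, 0.16))
            ] = reg.STRIATUM
    # MTL block with hippocampus (inferior) and amygdala (superior) inside
    for sgn in (-1, 1):
        xr = tuple(sorted((sgn * 0.18, sgn * 0.52)))
        if want(reg.MTL):
            labels[_box(x, y, z, xr, (-0.48, -0.08), (-0.32, 0.32))] = reg.MTL
        if want(reg.HIPPOCAMPUS):
            labels[_box(x, y, z, xr, (-0.44, -0.12), (-0.28, -0.02))] = (
                reg.HIPPOCAMPUS)
        if want(reg.AMYGDALA):
            labels[_box(x, y, z, xr, (-0.44, -0.12), (0.02, 0.28))] = reg.AMYGDALA
    return labels


def make_digital_phantom(
    shape: tuple[int, int, int] = (32, 32, 16),
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 3.0),
    region_params: dict[int, dict[str, float]] | None = None,
    hct: float = 0.44,
    jitter_sd: float = 0.0,
    db0_background_ppm: float = 0.05,
    seed: int = 0,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> PhantomTruth:
    """Construct the ground-truth digital phantom.

    Parameters are piecewise constant per region with optional multiplicative
    within-region Gaussian jitter of relative standard deviation ``jitter_sd``
    (labels are unaffected by jitter or seed). The macroscopic background
    field is a smooth second-order polynomial of peak scale
    ``db0_background_ppm``.

    Raises
    ------
    ValueError
        If a label present in the geometry has no parameter row.
    """
    if any(n < 8 for n in shape):
        raise ValueError("phantom grid must be at least 8 voxels per axis")
    params = region_params if region_params is not None else default_params(constants)
    labels = _build_labels(shape, wanted=set(params) if region_params is not None
                           else None)

    present = [int(v) for v in np.unique(labels) if v != reg.BACKGROUND]
    missing = [v for v in present if v not in params]
    if missing:
        names = [reg.LABEL_NAMES.get(v, str(v)) for v in missing]
        raise ValueError(f"missing parameter rows for labels: {names}")

    maps = {k: np.zeros(shape) for k in PARAM_KEYS}
    for label in present:
        m = labels == label
        for k in PARAM_KEYS:
            maps[k][m] = params[label][k]

    rng = np.random.default_rng(seed)
    if jitter_sd > 0:
        mask = labels > 0
        for k in PARAM_KEYS:
            jit = 1.0 + jitter_sd * rng.standard_normal(shape)
            maps[k] = np.where(mask, maps[k] * jit, maps[k])
        maps["yv"] = np.clip(maps["yv"], 0.0, constants.sao2)
        for k in ("dbv", "cbvv", "cbva"):
            maps[k] = np.clip(maps[k], 0.0, 0.2)
        maps["dbv"] = np.minimum(maps["dbv"], maps["cbvv"])
        for k in ("r2", "r2p_nh", "cbf"):
            maps[k] = np.clip(maps[k], 0.0, None)

    # smooth quadratic background field (ppm)
    x, yc, z = _normalized_coords(shape)
    db0 = db0_background_ppm * (0.3 + 0.4 * yc + 0.3 * z - 0.5 * x ** 2 + 0.2 * yc * z)

    truth = PhantomTruth(
        labels=labels,
        db0_background=db0,
        hct=hct,
        b0=constants.b0,
        voxel_size_mm=voxel_size_mm,
        **maps,
    )
    truth.validate(constants)
    return truth


def default_params(constants: PhysicsConstants = DEFAULT_CONSTANTS):
    return reg.default_region_params(constants)


# ---------------------------------------------------------------------------
# acquisition simulators
# ---------------------------------------------------------------------------

def _complex_noise(rng, shape, sd):
    return rng.normal(0.0, sd, shape) + 1j * rng.normal(0.0, sd, shape)


def simulate_ausfide(
    truth: PhantomTruth,
    acq: AcquisitionConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
    a_f: float = 100.0,
    a_e: float = 60.0,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> AusfideSeries:
    """Simulate the multi-echo SSFP FID/ECHO acquisition.

    Magnitudes follow the qBOLD forward model voxelwise; phase accrues from
    the total field offset (background plus the dipole field of the phantom's
    susceptibility distribution). Noise is additive circularly-symmetric
    complex Gaussian with per-quadrature standard deviation ``noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    state = truth.voxel_state(a_f=a_f, a_e=a_e)
    db0 = truth.db0_total(constants)
    fid = qbold_signal(state, acq, "FID", acq.te_fid, constants, db0_ppm=db0)
    echo = qbold_signal(state, acq, "ECHO", acq.te_echo, constants, db0_ppm=db0)
    mask = truth.brain_mask[..., None]
    fid = np.where(mask, fid, 0.0)
    echo = np.where(mask, echo, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fid = fid + _complex_noise(rng, fid.shape, noise_sd)
        echo = echo + _complex_noise(rng, echo.shape, noise_sd)
    return AusfideSeries(
        fid=fid,
        echo=echo,
        te_fid=acq.te_fid,
        te_echo=acq.te_echo,
        tr=acq.ausfide_tr,
        voxel_size_mm=truth.voxel_size_mm,
    )


def simulate_vsvsl(
    truth: PhantomTruth,
    acq: AcquisitionConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
    m0b: float = 100.0,
    static_scale: float = 100.0,
) -> LabeledPair:
    """Simulate the velocity-selective venous-labeling control/tag pair.

    The control minus tag difference equals 2 * kappa * M0b * CBVv per voxel
    before noise, with kappa = exp(-TI / T1b); static tissue is identical in
    both volumes and cancels in the subtraction.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    kappa = np.exp(-acq.vsvl_ti / acq.blood_t1)
    static = static_scale * truth.brain_mask.astype(float)
    venous = kappa * m0b * truth.cbvv
    control = static + venous
    tag = static - venous
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        control = control + rng.normal(0.0, noise_sd, control.shape)
        tag = tag + rng.normal(0.0, noise_sd, tag.shape)
    return LabeledPair(
        control=control, tag=tag, m0b=m0b, ti=acq.vsvl_ti, blood_t1=acq.blood_t1
    )


def simulate_pcasl(
    truth: PhantomTruth,
    acq: AcquisitionConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
    m0_scale: float = 100.0,
) -> PcaslSeries:
    """Simulate the pCASL control/label series and M0 volume.

    The per-pair label difference is generated by inverting the consensus
    single-compartment quantification formula, so that quantifying noiseless
    output returns the truth CBF map exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    m0 = m0_scale * truth.brain_mask.astype(float)
    lam = acq.partition_coefficient
    t1b = acq.blood_t1
    alpha = acq.labeling_efficiency
    tau = acq.pcasl_label_duration
    pld = acq.pcasl_pld
    dm = (
        truth.cbf
        * 2.0
        * alpha
        * t1b
        * (1.0 - np.exp(-tau / t1b))
        * m0
        * np.exp(-pld / t1b)
        / (6000.0 * lam)
    )
    n = acq.pcasl_n_pairs
    control = np.broadcast_to(m0 + dm / 2.0, (n, *truth.labels.shape)).copy()
    label = np.broadcast_to(m0 - dm / 2.0, (n, *truth.labels.shape)).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        control = control + rng.normal(0.0, noise_sd, control.shape)
        label = label + rng.normal(0.0, noise_sd, label.shape)
    return PcaslSeries(control=control, label=label, m0=m0)
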