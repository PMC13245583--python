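"""Estimation of the prior constraint maps feeding the constrained inversion.

From the multi-echo FID/ECHO magnitudes: R2, R2', R2* by weighted log-linear
monoexponential fits. From the FID phase: the macroscopic field offset dB0
(temporal unwrapping + weighted linear fit) and, after background removal and
Tikhonov-regularized dipole deconvolution, the relative susceptibility map.
From the venous-labeling pair: CBVv. From pCASL: CBF via the consensus
single-compartment quantification model.

The prior R2' estimate is deliberately monoexponential: the curvature of the
static-dephasing function at early echoes is left to the constrained fit,
which models it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AcquisitionConfig
from .constants import DEFAULT_CONSTANTS, PhysicsConstants
from .dipole import dipole_kernel
from .phantom import AusfideSeries, LabeledPair, PcaslSeries

__all__ = [
    "PriorMaps",
    "fit_decay_rates",
    "estimate_fieldmap",
    "invert_dipole",
    "quantify_cbvv",
    "quantify_cbf",
    "fit_all_priors",
]


@dataclass
class PriorMaps:
    """Measured constraint maps for the voxelwise inversion."""

    r2: np.ndarray
    r2p: np.ndarray
    r2star: np.ndarray
    db0: np.ndarray
    dchi: np.ndarray
    cbvv: np.ndarray
    cbf: np.ndarray | None = None
    quality: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def validate(self) -> None:
        finite = np.isfinite(self.r2star) & np.isfinite(self.r2) & np.isfinite(self.r2p)
        if not np.allclose(
            self.r2star[finite], (self.r2 + self.r2p)[finite], atol=1e-9
        ):
            raise ValueError("r2star must equal r2 + r2p")


def _weighted_loglinear_rate(mag: np.ndarray, te: np.ndarray, weight_power: float = 1.0):
    """Weighted LSQ of log magnitude vs te, weights |S|^weight_power, vectorized.

    Magnitude weighting down-weights the noisy late echoes without
    concentrating all leverage on the earliest echoes, where the curvature
    of the static-dephasing function biases a monoexponential fit most.

    Returns (rate, r_squared, valid) where rate = -slope.
    """
    valid = np.all(mag > 0, axis=-1)
    safe = np.where(mag > 0, mag, 1.0)
    logs = np.log(safe)
    w = safe ** weight_power
    sw = w.sum(-1)
    mx = (w * te).sum(-1) / sw
    my = (w * logs).sum(-1) / sw
    cov = (w * (te - mx[..., None]) * (logs - my[..., None])).sum(-1)
    var = (w * (te - mx[..., None]) ** 2).sum(-1)
    slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), np.nan)
    # weighted R^2 diagnostic
    resid = logs - (my[..., None] + slope[..., None] * (te - mx[..., None]))
    ss_res = (w * resid ** 2).sum(-1)
    ss_tot = (w * (logs - my[..., None]) ** 2).sum(-1)
    r2fit = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 1.0)
    return -slope, r2fit, valid


def fit_decay_rates(series: AusfideSeries, mask: np.ndarray, weight_power: float = 1.0):
    """Monoexponential decay rates from the FID and ECHO magnitudes.

    Per voxel: rate_FID from |FID| vs TE, rate_ECHO from |ECHO| vs TE, then
    R2 = (rate_FID + rate_ECHO)/2, R2' = (rate_FID - rate_ECHO)/2 and
    R2* = rate_FID. Negative R2' values are clipped to zero and flagged;
    all-zero voxels are marked invalid rather than raising.

    Returns
    -------
    (r2, r2p, r2star, info)
        Maps are NaN outside the mask or on invalid voxels; ``info`` carries
        the validity mask, the clip flags, and per-component fit R^2.
    """
    if series.fid.shape[-1] < 3 or series.echo.shape[-1] < 3:
        raise ValueError("need at least 3 echoes per component")
    mag_f = np.abs(series.fid)
    mag_e = np.abs(series.echo)
    rate_f, q_f, ok_f = _weighted_loglinear_rate(mag_f, series.te_fid, weight_power)
    # ECHO decays toward the refocusing point: the slope of log|S| vs TE is
    # -(R2 - R2'); the fitted "rate" below is therefore R2 - R2' directly.
    rate_e, q_e, ok_e = _weighted_loglinear_rate(mag_e, series.te_echo, weight_power)
    valid = mask & ok_f & ok_e
    r2 = np.where(valid, (rate_f + rate_e) / 2.0, np.nan)
    r2p = np.where(valid, (rate_f - rate_e) / 2.0, np.nan)
    clipped = valid & (r2p < 0)
    r2p = np.where(clipped, 0.0, r2p)
    r2star = r2 + r2p
    info = {
        "valid": valid,
        "r2p_clipped": clipped,
        "quality_fid": np.where(valid, q_f, np.nan),
        "quality_echo": np.where(valid, q_e, np.nan),
    }
    return r2, r2p, r2star, info


def estimate_fieldmap(
    series: AusfideSeries,
    mask: np.ndarray,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
):
    """Macroscopic field offset map (ppm) from the FID phase.

    Phase is unwrapped temporally across echoes, then fitted vs TE with
    magnitude-squared weights; the slope (rad/s) is converted to ppm of B0.
    Voxels whose inter-echo phase increment reaches pi (aliasing beyond the
    temporal unwrapping capture range) are flagged.
    """
    if series.fid.shape[-1] < 2:
        raise ValueError("need at least 2 FID echoes for the field map")
    phase = np.unwrap(np.angle(series.fid), axis=-1)
    w = np.abs(series.fid) ** 2
    te = series.te_fid
    sw = w.sum(-1)
    ok = mask & (sw > 0)
    sw_safe = np.where(sw > 0, sw, 1.0)
    mx = (w * te).sum(-1) / sw_safe
    my = (w * phase).sum(-1) / sw_safe
    var = (w * (te - mx[..., None]) ** 2).sum(-1)
    cov = (w * (te - mx[..., None]) * (phase - my[..., None])).sum(-1)
    slope = np.where(ok & (var > 0), cov / np.where(var > 0, var, 1.0), np.nan)
    dte = np.min(np.diff(te))
    aliased = ok & (np.abs(slope) * dte >= np.pi)
    db0 = slope / (constants.gamma * constants.b0 * 1e-6)
    db0 = np.where(ok, db0, np.nan)
    return db0, {"valid": ok, "aliased": aliased}


def polynomial_detrend(
    field: np.ndarray, mask: np.ndarray, order: int = 2
) -> np.ndarray:
    """Remove a low-order 3D polynomial fitted over the mask (background
    field removal). Returns the residual field, zero outside the mask."""
    shape = field.shape
    axes = [np.linspace(-1, 1, n) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    cols = [np.ones(shape)]
    if order >= 1:
        cols += [x, y, z]
    if order >= 2:
        cols += [x * y, x * z, y * z, x ** 2, y ** 2, z ** 2]
    if order >= 3:
        raise ValueError("polynomial detrend supports order <= 2")
    a = np.stack([c[mask] for c in cols], axis=1)
    beta, *_ = np.linalg.lstsq(a, field[mask], rcond=None)
    trend = sum(b * c for b, c in zip(beta, cols))
    return np.where(mask, field - trend, 0.0)


def invert_dipole(
    field_ppm: np.ndarray,
    mask: np.ndarray,
    reg: float = 1e-2,
    detrend_order: int | None = 2,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Susceptibility map (ppm) by Tikhonov-regularized dipole deconvolution.

    chi = IFFT[ conj(D) FFT(field) / (|D|^2 + reg) ] after optional polynomial
    background removal (``detrend_order=None`` skips it). Linear in the field.
    """
    if reg <= 0:
        raise ValueError("regularization must be > 0")
    if not np.all(np.isfinite(field_ppm[mask])):
        raise ValueError("field must be finite inside the mask")
    f = np.where(mask, field_ppm, 0.0)
    if detrend_order is not None:
        f = polynomial_detrend(f, mask, detrend_order)
    d = dipole_kernel(f.shape, voxel_size_mm)
    chi = np.real(np.fft.ifftn(np.conj(d) * np.fft.fftn(f) / (d ** 2 + reg)))
    return np.where(mask, chi, 0.0)


def quantify_cbvv(pair: LabeledPair, acq: AcquisitionConfig, m0b: float):
    """Venous blood volume fraction map from the control/tag difference:
    CBVv = (control - tag) / (2 kappa M0b), kappa = exp(-TI / T1b).
    Negative values are clipped to zero with a flag map."""
    if m0b <= 0:
        raise ValueError("m0b must be > 0")
    if pair.control.shape != pair.tag.shape:
        raise ValueError("control and tag volumes must be congruent")
    kappa = np.exp(-acq.vsvl_ti / acq.blood_t1)
    cbvv = (pair.control - pair.tag) / (2.0 * kappa * m0b)
    clipped = cbvv < 0
    return np.where(clipped, 0.0, cbvv), {"clipped": clipped}


def quantify_cbf(series: PcaslSeries, acq: AcquisitionConfig):
    """CBF map (mL/100 g/min) via the consensus single-compartment model:

    CBF = 6000 lambda dM exp(PLD/T1b) / (2 alpha T1b (1 - exp(-tau/T1b)) M0)

    with dM the mean control-label difference across pairs. Voxels with
    non-positive M0 are flagged invalid (NaN).
    """
    dm = np.mean(series.control - series.label, axis=0)
    m0 = series.m0
    lam = acq.partition_coefficient
    t1b = acq.blood_t1
    alpha = acq.labeling_efficiency
    tau = acq.pcasl_label_duration
    pld = acq.pcasl_pld
    valid = m0 > 0
    denom = 2.0 * alpha * t1b * (1.0 - np.exp(-tau / t1b)) * np.where(valid, m0, 1.0)
    cbf = 6000.0 * lam * dm * np.exp(pld / t1b) / denom
    cbf = np.where(valid, cbf, np.nan)
    return cbf, {"valid": valid}


def fit_all_priors(
    ausfide: AusfideSeries,
    vsvsl: LabeledPair,
    pcasl: PcaslSeries | None,
    acq: AcquisitionConfig,
    mask: np.ndarray,
    m0b: float = 100.0,
    qsm_reg: float = 1e-2,
    detrend_order: int | None = 2,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> PriorMaps:
    """Convenience driver producing all five prior maps (plus CBF)."""
    r2, r2p, r2star, rate_info = fit_decay_rates(ausfide, mask)
    db0, field_info = estimate_fieldmap(ausfide, mask, constants)
    db0_filled = np.where(np.isfinite(db0), db0, 0.0)
    dchi = invert_dipole(
        db0_filled, mask, reg=qsm_reg, detrend_order=detrend_order,
        voxel_size_mm=ausfide.voxel_size_mm,
    )
    cbvv, cbvv_info = quantify_cbvv(vsvsl, acq, m0b)
    cbf = None
    flags = {**rate_info, **{f"field_{k}": v for k, v in field_info.items()},
             "cbvv_clipped": cbvv_info["clipped"]}
    if pcasl is not None:
        cbf, cbf_info = quantify_cbf(pcasl, acq)
        flags["cbf_valid"] = cbf_info["valid"]
    priors = PriorMaps(
        r2=r2, r2p=r2p, r2star=r2star, db0=db0, dchi=dchi,
        cbvv=np.where(mask, cbvv, np.nan), cbf=cbf,
        quality=rate_info["quality_fid"], flags=flags,
    )
    priors.validate()
    return priors
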