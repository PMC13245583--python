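"""Closed-form signal models shared by the simulator and the constrained fitter.

The qBOLD forward model describes the extravascular signal around a random
network of venous vessels in the static dephasing regime: the reversible
decay is ``exp(-DBV * fc(delta_omega * t))`` where ``fc`` is the isotropic
static-dephasing function and ``delta_omega`` the characteristic frequency
set by the susceptibility difference between deoxygenated venous blood and
tissue. On top sit the irreversible decay R2 and a non-heme reversible rate
R2'nh (iron, myelin), so that in the linear regime of ``fc`` the FID decays
at R2 + R2' and the echo component at R2 - R2', with
R2' = DBV * delta_omega + R2'nh.

Amplitudes of the FID and ECHO components are free scales: the steady-state
amplitude model of the underlying SSFP sequence is deliberately not part of
the contract here, and both the simulator and the fitter treat A_F, A_E as
unknown per-voxel scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import j0

from .config import AcquisitionConfig
from .constants import DEFAULT_CONSTANTS, PhysicsConstants

__all__ = [
    "VoxelState",
    "static_dephasing_fc",
    "delta_omega",
    "qbold_signal",
    "susceptibility_model",
    "r2prime_model",
    "fick_cmro2",
    "oef_from_yv",
    "yv_from_oef",
]


# ---------------------------------------------------------------------------
# static dephasing function fc
# ---------------------------------------------------------------------------

def _fc_integrand(u: float, x: float) -> float:
    z = 1.5 * x * u
    if z < 1e-3:
        # series for 1 - J0(z) avoids catastrophic cancellation at small z
        one_minus_j0 = z * z / 4.0 - z ** 4 / 64.0
    else:
        one_minus_j0 = 1.0 - j0(z)
    return (2.0 + u) * np.sqrt(1.0 - u) * one_minus_j0 / (u * u)


def _fc_quad(x: float) -> float:
    """Adaptive-quadrature evaluation of fc at a scalar x >= 0."""
    if x == 0.0:
        return 0.0
    val, _ = quad(_fc_integrand, 0.0, 1.0, args=(x,), limit=200)
    return val / 3.0


# Lazily built lookup table; dense near the curved region, coarser in the
# asymptotically linear tail. Beyond the table fc is extended with unit slope.
_FC_TABLE: tuple[np.ndarray, np.ndarray] | None = None
_FC_XMAX = 60.0


def _fc_table() -> tuple[np.ndarray, np.ndarray]:
    global _FC_TABLE
    if _FC_TABLE is None:
        xs = np.concatenate(
            [np.linspace(0.0, 2.0, 801), np.linspace(2.0, _FC_XMAX, 1401)[1:]]
        )
        ys = np.array([_fc_quad(float(x)) for x in xs])
        _FC_TABLE = (xs, ys)
    return _FC_TABLE


def static_dephasing_fc(x) -> np.ndarray | float:
    """Isotropic static-dephasing function fc(x).

    fc(x) = (1/3) * int_0^1 (2+u) sqrt(1-u) (1 - J0(1.5 x u)) / u^2 du,
    evaluated by adaptive quadrature on a dense grid and interpolated.
    fc(0) = 0, fc ~ 0.3 x^2 for x << 1, and fc approaches unit slope for
    x >> 1 so that DBV * fc(dw * t) contributes R2' = DBV * dw at long times.

    Parameters
    ----------
    x:
        Dimensionless argument (delta_omega * time), scalar or array, >= 0.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("fc argument must be >= 0")
    xs, ys = _fc_table()
    out = np.interp(x_arr, xs, ys)
    tail = x_arr > _FC_XMAX
    if np.any(tail):
        out = np.where(tail, ys[-1] + (x_arr - _FC_XMAX), out)
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(out)
    return out


def delta_omega(hct, yv, constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Characteristic dephasing frequency of venous blood, rad/s.

    delta_omega = (4 pi / 3) * gamma * B0 * dchi_do * Hct * (1 - Yv), with the
    susceptibility scale in ppm (the 1e-6 applied here).
    """
    hct_arr = np.asarray(hct, dtype=float)
    yv_arr = np.asarray(yv, dtype=float)
    if np.any((hct_arr < 0) | (hct_arr > 1)):
        raise ValueError("hct must be in [0, 1]")
    if np.any((yv_arr < 0) | (yv_arr > 1)):
        raise ValueError("yv must be in [0, 1]")
    out = (
        constants.gamma
        * constants.b0
        * constants.dchi_do_eff
        * 1e-6
        * hct_arr
        * (1.0 - yv_arr)
    )
    if np.isscalar(hct) and np.isscalar(yv):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# voxel state and signal model
# ---------------------------------------------------------------------------

@dataclass
class VoxelState:
    """Per-voxel physiological state entering the qBOLD forward model.

    Fields may be scalars or congruent arrays (broadcast voxelwise).
    """

    yv: np.ndarray | float
    dbv: np.ndarray | float
    r2: np.ndarray | float
    r2p_nh: np.ndarray | float
    chi_nb: np.ndarray | float
    cbvv: np.ndarray | float
    hct: float
    cbva: np.ndarray | float = 0.01
    a_f: np.ndarray | float = 1.0
    a_e: np.ndarray | float = 1.0

    def validate(self, constants: PhysicsConstants = DEFAULT_CONSTANTS) -> None:
        for name, hi in (("dbv", 0.2), ("cbvv", 0.2), ("cbva", 0.2)):
            v = np.asarray(getattr(self, name))
            if np.any((v < 0) | (v > hi)):
                raise ValueError(f"{name} must be within [0, {hi}]")
        yv = np.asarray(self.yv)
        if np.any((yv < 0) | (yv > constants.sao2 + 1e-12)):
            raise ValueError("yv must be within [0, sao2]")
        for name in ("r2", "r2p_nh"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be >= 0")


def qbold_signal(
    state: VoxelState,
    acq: AcquisitionConfig,
    component: str,
    te,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
    db0_ppm=0.0,
):
    """Complex qBOLD signal of one AUSFIDE component at echo time(s) ``te``.

    FID:  A_F exp(-R2 te) exp(-DBV fc(dw te)) exp(-R2'nh te), phase accruing
    as gamma B0 dB0 te.
    ECHO: A_E exp(-R2 te) exp(-DBV fc(dw (TR - te))) exp(-R2'nh (TR - te)),
    reversible dephasing and macroscopic phase referenced to the refocusing
    point at TR, consistent with effective decay rates R2 + R2' (FID) and
    R2 - R2' (ECHO) in the linear regime of fc.
    """
    te_arr = np.asarray(te, dtype=float)
    dw = delta_omega(state.hct, state.yv, constants)
    dw = np.asarray(dw)[..., None] if np.ndim(dw) else dw
    r2 = np.asarray(state.r2)[..., None] if np.ndim(state.r2) else state.r2
    dbv = np.asarray(state.dbv)[..., None] if np.ndim(state.dbv) else state.dbv
    r2p_nh = (
        np.asarray(state.r2p_nh)[..., None] if np.ndim(state.r2p_nh) else state.r2p_nh
    )
    db0 = np.asarray(db0_ppm)[..., None] if np.ndim(db0_ppm) else db0_ppm

    if component.upper() == "FID":
        a = np.asarray(state.a_f)[..., None] if np.ndim(state.a_f) else state.a_f
        mag = (
            a
            * np.exp(-r2 * te_arr)
            * np.exp(-dbv * static_dephasing_fc(dw * te_arr))
            * np.exp(-r2p_nh * te_arr)
        )
        phase = constants.gamma * constants.b0 * db0 * 1e-6 * te_arr
    elif component.upper() == "ECHO":
        if np.any(te_arr >= acq.ausfide_tr):
            raise ValueError("ECHO echo times must be < TR")
        tau = acq.ausfide_tr - te_arr
        a = np.asarray(state.a_e)[..., None] if np.ndim(state.a_e) else state.a_e
        mag = (
            a
            * np.exp(-r2 * te_arr)
            * np.exp(-dbv * static_dephasing_fc(dw * tau))
            * np.exp(-r2p_nh * tau)
        )
        phase = -constants.gamma * constants.b0 * db0 * 1e-6 * tau
    else:
        raise ValueError(f"component must be 'FID' or 'ECHO', got {component!r}")

    out = mag * np.exp(1j * phase)
    if np.isscalar(te) and out.ndim and out.shape[-1] == 1:
        out = out[..., 0]
    return out


def susceptibility_model(
    state: VoxelState, constants: PhysicsConstants = DEFAULT_CONSTANTS
):
    """Voxel susceptibility (ppm) from the four intravoxel pools.

    Arterial blood (deoxy fraction 1 - SaO2), venous blood (deoxy fraction
    1 - Yv), the fully oxygenated blood baseline chi_oxy, and non-blood
    tissue chi_nb, volume-weighted:

        Psi = CBVa [chi_oxy + Hct dchi (1 - SaO2)]
            + CBVv [chi_oxy + Hct dchi (1 - Yv)]
            + (1 - CBVa - CBVv) chi_nb

    with dchi the effective deoxy-blood scale (same convention as
    :func:`delta_omega`).
    """
    cbva = np.asarray(state.cbva, dtype=float)
    cbvv = np.asarray(state.cbvv, dtype=float)
    if np.any(cbva + cbvv > 1.0 + 1e-12):
        raise ValueError("CBVa + CBVv must not exceed 1")
    dchi = constants.dchi_do_eff
    hct = state.hct
    chi_art = constants.chi_oxy + hct * dchi * (1.0 - constants.sao2)
    chi_ven = constants.chi_oxy + hct * dchi * (1.0 - np.asarray(state.yv, dtype=float))
    out = (
        cbva * chi_art
        + cbvv * chi_ven
        + (1.0 - cbva - cbvv) * np.asarray(state.chi_nb, dtype=float)
        + constants.chi_reference_offset
    )
    if out.ndim == 0:
        return float(out)
    return out


def r2prime_model(state: VoxelState, constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Total reversible rate R2' (s^-1), heme plus non-heme:
    Y = DBV * delta_omega(Hct, Yv) + R2'nh."""
    out = np.asarray(state.dbv, dtype=float) * delta_omega(
        state.hct, state.yv, constants
    ) + np.asarray(state.r2p_nh, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# oxygen metabolism
# ---------------------------------------------------------------------------

def fick_cmro2(cbf, hct, oef, constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Cerebral metabolic rate of oxygen via Fick's principle.

    CMRO2 = CBF * Ca * SaO2 * OEF with Ca = Hct * C_rbc. Units: CBF in
    mL/100 g/min, OEF as a fraction, result in umol O2/100 g/min.
    """
    cbf_arr = np.asarray(cbf, dtype=float)
    oef_arr = np.asarray(oef, dtype=float)
    hct_arr = np.asarray(hct, dtype=float)
    if np.any(cbf_arr[np.isfinite(cbf_arr)] < 0):
        raise ValueError("cbf must be >= 0")
    if np.any(hct_arr[np.isfinite(hct_arr)] < 0):
        raise ValueError("hct must be >= 0")
    finite = np.isfinite(oef_arr)
    if np.any((oef_arr[finite] < 0) | (oef_arr[finite] > 1)):
        raise ValueError("oef must be a fraction in [0, 1]")
    out = cbf_arr * (hct_arr * constants.c_rbc) * constants.sao2 * oef_arr
    if out.ndim == 0:
        return float(out)
    return out


def oef_from_yv(yv, constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Oxygen extraction fraction from venous saturation: (SaO2 - Yv)/SaO2.

    Values of yv above SaO2 (unphysical, produced only by noise) are clipped
    to OEF = 0; a boolean ``clipped`` array is returned alongside when the
    input is an array.
    """
    yv_arr = np.asarray(yv, dtype=float)
    oef = (constants.sao2 - yv_arr) / constants.sao2
    clipped = oef < 0
    oef = np.where(clipped, 0.0, oef)
    if np.ndim(yv) == 0:
        import warnings

        if clipped:
            warnings.warn("yv exceeds SaO2; OEF clipped to 0", stacklevel=2)
        return float(oef)
    return oef, clipped


def yv_from_oef(oef, constants: PhysicsConstants = DEFAULT_CONSTANTS):
    """Inverse of :func:`oef_from_yv`: Yv = SaO2 * (1 - OEF)."""
    out = constants.sao2 * (1.0 - np.asarray(oef, dtype=float))
    if np.ndim(oef) == 0:
        return float(out)
    return out
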