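"""Constrained voxelwise qBOLD inversion for OEF and CMRO2 mapping.

Per voxel, the four unknowns Theta = {Yv, DBV, R2'nh, chi_nb} are estimated
by bounded nonlinear least squares on the stacked residual

    [ |y_FID| - Xi_FID(Theta) ;
      |y_ECHO| - Xi_ECHO(Theta) ;
      sqrt(w) (dchi_prior - Psi(Theta)) ;
      sqrt(p) (R2'_prior - Y(Theta)) ]

where Xi is the qBOLD forward model with R2 fixed from its measured prior,
Psi the four-pool susceptibility model (venous volume from the measured CBVv
prior), and Y = DBV delta_omega + R2'nh the R2' decomposition. The FID and
ECHO amplitudes are profiled out by an exact linear solve at every iterate
(variable projection), so the nonlinear search runs over four parameters
only. The susceptibility and R2' penalties regularize the otherwise poorly
conditioned Yv/DBV trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .config import AcquisitionConfig, FitWeights
from .constants import DEFAULT_CONSTANTS, PhysicsConstants
from .phantom import AusfideSeries
from .physics import (
    delta_omega,
    fick_cmro2,
    oef_from_yv,
    static_dephasing_fc,
)
from .priors import PriorMaps

__all__ = ["QboldResult", "fit_voxel", "fit_volume", "cmro2_map"]

_PARAM_ORDER = ("yv", "dbv", "r2p_nh", "chi_nb")


@dataclass
class QboldResult:
    """Voxelwise estimates of the constrained qBOLD inversion."""

    yv: np.ndarray
    oef: np.ndarray
    dbv: np.ndarray
    r2p_nh: np.ndarray
    chi_nb: np.ndarray
    residual_norm: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray
    mask: np.ndarray
    cmro2: np.ndarray | None = None
    summary: dict = field(default_factory=dict)


def _model_shapes(theta, te_fid, te_echo, tr, r2, hct, constants):
    """Unit-amplitude FID and ECHO model magnitudes for parameters theta."""
    yv, dbv, r2p_nh, _ = theta
    dw = delta_omega(hct, float(np.clip(yv, 0.0, 1.0)), constants)
    m_f = np.exp(-r2 * te_fid - dbv * static_dephasing_fc(dw * te_fid) - r2p_nh * te_fid)
    tau = tr - te_echo
    m_e = np.exp(-r2 * te_echo - dbv * static_dephasing_fc(dw * tau) - r2p_nh * tau)
    return m_f, m_e


def _psi(theta, cbvv, cbva, hct, constants):
    yv, _, _, chi_nb = theta
    dchi = constants.dchi_do_eff
    chi_art = constants.chi_oxy + hct * dchi * (1.0 - constants.sao2)
    chi_ven = constants.chi_oxy + hct * dchi * (1.0 - yv)
    return cbva * chi_art + cbvv * chi_ven + (1.0 - cbva - cbvv) * chi_nb


def _y_model(theta, hct, constants):
    yv, dbv, r2p_nh, _ = theta
    return dbv * delta_omega(hct, float(np.clip(yv, 0.0, 1.0)), constants) + r2p_nh


def _profiled_amplitude(y, m):
    mm = float(np.dot(m, m))
    if mm <= 0:
        return 0.0
    return max(float(np.dot(y, m)) / mm, 0.0)


def fit_voxel(
    y_fid: np.ndarray,
    y_echo: np.ndarray,
    priors: dict,
    hct: float,
    acq: AcquisitionConfig,
    weights: FitWeights | None = None,
    cbva: float = 0.01,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
    dbv_equals_cbvv: bool = False,
    return_trace: bool = False,
) -> dict:
    """Solve the constrained inversion for a single voxel.

    Parameters
    ----------
    y_fid, y_echo:
        Echo magnitudes (complex input is reduced to magnitude).
    priors:
        Dict with keys ``r2`` (fixed in the forward model), ``r2p``,
        ``dchi``, ``cbvv`` (venous volume in Psi and the DBV initializer).
    weights:
        Regularization weights / solver options; ``"auto"`` balances each
        penalty against the data term at the initialization point.
    dbv_equals_cbvv:
        If True, DBV is pinned to the CBVv prior (hard-constraint variant)
        instead of remaining free.

    Returns
    -------
    dict with the four parameter estimates, ``oef``, profiled amplitudes,
    residual norm, convergence flag, iteration count, and (optionally) the
    trace of accepted objective values.
    """
    if weights is None:
        weights = FitWeights()
    y_f = np.abs(np.asarray(y_fid, dtype=complex)).astype(float)
    y_e = np.abs(np.asarray(y_echo, dtype=complex)).astype(float)
    n_echo = y_f.size + y_e.size
    if y_f.size < 3 or y_e.size < 3:
        raise ValueError("need at least 3 echoes per component")
    for key in ("r2", "r2p", "dchi", "cbvv"):
        if key not in priors or not np.isfinite(priors[key]):
            raise ValueError(f"prior {key!r} missing or non-finite")
    if not np.all(np.isfinite(y_f)) or not np.all(np.isfinite(y_e)):
        return _invalid_result()
    if np.max(y_f) <= 0 or np.max(y_e) <= 0:
        return _invalid_result()

    r2 = float(priors["r2"])
    r2p_prior = float(priors["r2p"])
    dchi_prior = float(priors["dchi"])
    cbvv = float(np.clip(priors["cbvv"], 0.0, 0.2))
    te_f, te_e, tr = acq.te_fid, acq.te_echo, acq.ausfide_tr

    bounds = weights.bounds
    lo = np.array([bounds[k][0] for k in _PARAM_ORDER])
    hi = np.array([bounds[k][1] for k in _PARAM_ORDER])

    # --- initialization -----------------------------------------------------
    dbv0 = float(np.clip(cbvv if cbvv > 0 else 0.02, lo[1], hi[1]))
    r2p_nh0 = float(np.clip(0.2 * r2p_prior, lo[2], hi[2]))
    # invert Y = DBV dw(Yv) + R2'nh for Yv at the initial DBV and R2'nh
    dw_scale = constants.gamma * constants.b0 * constants.dchi_do_eff * 1e-6 * hct
    heme = max(r2p_prior - r2p_nh0, 0.0)
    yv0 = 1.0 - heme / (dbv0 * dw_scale) if dbv0 * dw_scale > 0 else 0.6
    yv0 = float(np.clip(yv0, lo[0], hi[0]))
    chi0 = float(np.clip(dchi_prior, lo[3], hi[3]))
    x0 = np.array([yv0, dbv0, r2p_nh0, chi0])

    if dbv_equals_cbvv:
        lo = lo.copy()
        hi = hi.copy()
        lo[1] = max(cbvv - 1e-9, 0.0)
        hi[1] = cbvv + 1e-9
        x0[1] = cbvv

    # --- penalty weights ----------------------------------------------------
    def data_residual(theta):
        m_f, m_e = _model_shapes(theta, te_f, te_e, tr, r2, hct, constants)
        a_f = _profiled_amplitude(y_f, m_f)
        a_e = _profiled_amplitude(y_e, m_e)
        return np.concatenate([y_f - a_f * m_f, y_e - a_e * m_e])

    def resolve_weight(wval, penalty0, floor):
        # balance heuristic: penalty contribution at the initialization equals
        # the data term divided by the echo count; the floor (a characteristic
        # squared penalty scale) keeps the weight finite when the initializer
        # happens to satisfy the penalty exactly
        if wval == "auto":
            data0 = float(np.sum(data_residual(x0) ** 2))
            return (data0 / n_echo) / max(penalty0, floor)
        return float(wval)

    # floors are characteristic squared prior-vs-model mismatch scales
    # (0.05 ppm for susceptibility, 2 s^-1 for R2'), preventing the penalty
    # from dominating when the initializer happens to satisfy it
    pen_chi0 = (dchi_prior - _psi(x0, cbvv, cbva, hct, constants)) ** 2
    pen_r2p0 = (r2p_prior - _y_model(x0, hct, constants)) ** 2
    w = resolve_weight(weights.w, pen_chi0, floor=2.5e-3)
    p = resolve_weight(weights.p, pen_r2p0, floor=4.0)
    sqrt_w, sqrt_p = np.sqrt(w), np.sqrt(p)

    def make_residual(r2_cur):
        def residual(theta):
            m_f, m_e = _model_shapes(theta, te_f, te_e, tr, r2_cur, hct, constants)
            a_f = _profiled_amplitude(y_f, m_f)
            a_e = _profiled_amplitude(y_e, m_e)
            pen = np.array(
                [
                    sqrt_w * (dchi_prior - _psi(theta, cbvv, cbva, hct, constants)),
                    sqrt_p * (r2p_prior - _y_model(theta, hct, constants)),
                ]
            )
            return np.concatenate([y_f - a_f * m_f, y_e - a_e * m_e, pen])
        return residual

    def refit_r2(theta):
        # exact weighted log-linear re-estimate of R2 given theta: both
        # components share the slope -R2 vs TE once the reversible terms are
        # removed, with separate intercepts (the free amplitudes)
        yv, dbv, r2p_nh, _ = theta
        dw = delta_omega(hct, float(np.clip(yv, 0.0, 1.0)), constants)
        pos_f, pos_e = y_f > 0, y_e > 0
        if pos_f.sum() < 3 or pos_e.sum() < 3:
            return None
        z_f = (np.log(y_f[pos_f]) + dbv * static_dephasing_fc(dw * te_f[pos_f])
               + r2p_nh * te_f[pos_f])
        tau = tr - te_e
        z_e = (np.log(y_e[pos_e]) + dbv * static_dephasing_fc(dw * tau[pos_e])
               + r2p_nh * tau[pos_e])
        num = den = 0.0
        for z, t, yy in ((z_f, te_f[pos_f], y_f[pos_f]),
                         (z_e, te_e[pos_e], y_e[pos_e])):
            wgt = yy ** 2
            sw = wgt.sum()
            tm = (wgt * t).sum() / sw
            zm = (wgt * z).sum() / sw
            num += (wgt * (t - tm) * (z - zm)).sum()
            den += (wgt * (t - tm) ** 2).sum()
        if den <= 0:
            return None
        return -num / den

    def solve(start, r2_cur):
        return least_squares(
            make_residual(r2_cur),
            np.clip(start, lo, hi),
            bounds=(lo, hi),
            method="trf",
            xtol=weights.tol,
            ftol=weights.tol,
            gtol=None,
            max_nfev=weights.max_iter * 10,
        )

    # --- multistart over a Yv grid -------------------------------------------
    starts = [x0]
    if weights.multistart > 1:
        grid = np.linspace(lo[0] + 0.02, hi[0] - 0.02, weights.multistart)
        starts = [np.array([g, x0[1], x0[2], x0[3]]) for g in grid]
        starts.insert(0, x0)

    best = None
    trace = []
    for start in starts:
        sol = solve(start, r2)
        trace.append(sol.cost)
        # lowest objective wins; ties broken toward lowest DBV for determinism
        key = (round(sol.cost, 14), round(sol.x[1], 10))
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]

    # --- auto-weight rebalancing pass ----------------------------------------
    # The init-based balance overweights the penalties when the data can be
    # fitted almost exactly; rebalance against the converged per-echo data
    # misfit (the noise level, in effect) and re-solve once.
    if weights.w == "auto" or weights.p == "auto":
        data_conv = float(np.sum(data_residual(sol.x) ** 2))
        if weights.w == "auto":
            w = (data_conv / n_echo) / max(pen_chi0, 2.5e-3)
            sqrt_w = np.sqrt(w)
        if weights.p == "auto":
            p = (data_conv / n_echo) / max(pen_r2p0, 4.0)
            sqrt_p = np.sqrt(p)
        sol = solve(sol.x, r2)
        trace.append(sol.cost)

    # outer self-consistency loop: re-estimate R2 from the data at the current
    # theta, then re-solve theta with the refined R2 (warm-started)
    r2_fit = r2
    for _ in range(weights.refine_r2):
        r2_new = refit_r2(sol.x)
        if r2_new is None or not np.isfinite(r2_new) or r2_new < 0:
            break
        if abs(r2_new - r2_fit) < 1e-10:
            r2_fit = r2_new
            break
        r2_fit = r2_new
        sol = solve(sol.x, r2_fit)
        trace.append(sol.cost)

    theta = sol.x
    m_f, m_e = _model_shapes(theta, te_f, te_e, tr, r2_fit, hct, constants)
    out = {
        "yv": float(theta[0]),
        "dbv": float(theta[1]),
        "r2p_nh": float(theta[2]),
        "chi_nb": float(theta[3]),
        "oef": float(oef_from_yv(min(theta[0], constants.sao2), constants)),
        "a_f": _profiled_amplitude(y_f, m_f),
        "a_e": _profiled_amplitude(y_e, m_e),
        "r2": float(r2_fit),
        "residual_norm": float(np.sqrt(2.0 * sol.cost)),
        "converged": bool(sol.status > 0),
        "iterations": int(sol.nfev),
        "valid": True,
        "w": w,
        "p": p,
    }
    if return_trace:
        out["trace"] = trace
    return out


def _invalid_result() -> dict:
    return {
        "yv": np.nan, "dbv": np.nan, "r2p_nh": np.nan, "chi_nb": np.nan,
        "oef": np.nan, "a_f": np.nan, "a_e": np.nan, "r2": np.nan,
        "residual_norm": np.nan, "converged": False, "iterations": 0,
        "valid": False, "w": np.nan, "p": np.nan,
    }


def fit_volume(
    series: AusfideSeries,
    priors: PriorMaps,
    hct: float,
    acq: AcquisitionConfig,
    weights: FitWeights | None = None,
    mask: np.ndarray | None = None,
    cbva: float = 0.01,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
    dbv_equals_cbvv: bool = False,
) -> QboldResult:
    """Apply :func:`fit_voxel` over a mask; deterministic given inputs.

    Voxels with missing priors or degenerate signal are marked invalid (NaN
    maps, converged False) rather than raising.
    """
    shape = series.fid.shape[:-1]
    if priors.r2.shape != shape:
        raise ValueError(
            f"prior grid {priors.r2.shape} does not match series grid {shape}"
        )
    if mask is None:
        mask = np.isfinite(priors.r2)
    if mask.shape != shape:
        raise ValueError("mask grid does not match series grid")
    if weights is None:
        weights = FitWeights()

    maps = {k: np.full(shape, np.nan) for k in
            ("yv", "oef", "dbv", "r2p_nh", "chi_nb", "residual_norm")}
    converged = np.zeros(shape, dtype=bool)
    iterations = np.zeros(shape, dtype=np.int32)

    idx = np.argwhere(mask)
    n_conv = 0
    iter_counts = []
    for i, j, k in idx:
        pri = {
            "r2": priors.r2[i, j, k],
            "r2p": priors.r2p[i, j, k],
            "dchi": priors.dchi[i, j, k],
            "cbvv": priors.cbvv[i, j, k],
        }
        if not all(np.isfinite(v) for v in pri.values()):
            continue
        res = fit_voxel(
            series.fid[i, j, k], series.echo[i, j, k], pri, hct, acq,
            weights, cbva, constants, dbv_equals_cbvv,
        )
        if not res["valid"]:
            continue
        for key in maps:
            maps[key][i, j, k] = res[key]
        converged[i, j, k] = res["converged"]
        iterations[i, j, k] = res["iterations"]
        n_conv += res["converged"]
        iter_counts.append(res["iterations"])

    n_masked = len(idx)
    summary = {
        "n_voxels": int(n_masked),
        "fraction_converged": float(n_conv / n_masked) if n_masked else 0.0,
        "median_iterations": float(np.median(iter_counts)) if iter_counts else 0.0,
    }
    return QboldResult(
        yv=maps["yv"], oef=maps["oef"], dbv=maps["dbv"],
        r2p_nh=maps["r2p_nh"], chi_nb=maps["chi_nb"],
        residual_norm=maps["residual_norm"], converged=converged,
        iterations=iterations, mask=mask, summary=summary,
    )


def cmro2_map(
    result: QboldResult,
    cbf: np.ndarray,
    hct: float,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Voxelwise CMRO2 (umol/100 g/min) from fitted OEF and a CBF map.

    Non-finite OEF or CBF voxels propagate as NaN.
    """
    if cbf.shape != result.oef.shape:
        raise ValueError("CBF grid does not match the fit result grid")
    if not 0.0 < hct < 1.0:
        raise ValueError("hct must be a fraction in (0, 1)")
    valid = np.isfinite(result.oef) & np.isfinite(cbf)
    out = np.full(result.oef.shape, np.nan)
    out[valid] = fick_cmro2(cbf[valid], hct, np.clip(result.oef[valid], 0, 1),
                            constants)
    result.cmro2 = out
    return out
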