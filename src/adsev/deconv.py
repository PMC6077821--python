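"""Truncated-SVD deconvolution of tissue curves into CBF/CBV/MTT maps.

The tissue curve is modeled as Ct = A x with A the lower-triangular
Toeplitz convolution matrix of the AIF (A[i, j] = dt * Ca(t_{i-j})) and
x = F_si * R the flow-scaled residue.  A is inverted by SVD with singular
values below ``threshold_frac * sigma_max`` zeroed (the standard
regularization against the ill-conditioning of bolus kernels);
CBF = 6000 * max(x).  CBV is the ratio of trapezoid areas,
CBV = 100 * ∫Ct / ∫Ca, and MTT = (CBV/CBF) * 60 by the central-volume
theorem, reported 0 where the flow estimate is below epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from adsev.aif_select import AifResult
from adsev.dsc_phantom import CBF_TO_SI, ConcCurve

__all__ = [
    "PerfusionMaps", "build_convolution_matrix", "svd_deconvolve",
    "compute_cbv", "perfusion_maps",
]

#: flow estimates (1/s) below this are treated as no-flow for the MTT ratio
FLOW_EPSILON_SI = 1e-9


def build_convolution_matrix(aif: ConcCurve) -> np.ndarray:
    """Lower-triangular Toeplitz matrix A with A[i, j] = dt * aif(t_{i-j})."""
    first_col = aif.grid.dt * aif.values
    return toeplitz(first_col, np.zeros_like(first_col))


def _truncated_pinv(A: np.ndarray, threshold_frac: float
                    ) -> tuple[np.ndarray, dict]:
    U, s, Vt = np.linalg.svd(A)
    if s[0] <= 0:
        warnings.warn("AIF convolution matrix is identically zero")
        return np.zeros_like(A.T), {"n_kept": 0, "condition": np.inf}
    keep = s >= threshold_frac * s[0]
    if not keep.any():
        warnings.warn("all singular values fall below the truncation "
                      "threshold; returning a zero inverse")
        return np.zeros_like(A.T), {"n_kept": 0, "condition": np.inf}
    s_inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    s_inv[s <= 0] = 0.0
    pinv = (Vt.T * s_inv) @ U.T
    diag = {
        "n_kept": int(keep.sum()),
        "n_singular_values": int(s.size),
        "condition": float(s[0] / s[keep].min()),
    }
    return pinv, diag


def svd_deconvolve(ct: ConcCurve, aif: ConcCurve,
                   threshold_frac: float = 0.2
                   ) -> tuple[ConcCurve, float]:
    """Solve A x = ct by truncated SVD; return (x, CBF in mL/100g/min).

    x estimates the flow-scaled residue F_si * R(t), so CBF is its
    maximum rescaled by 6000.
    """
    if not ct.same_grid(aif):
        raise ValueError("tissue curve and AIF are on different grids")
    if aif.values.max() <= 0:
        raise ValueError("AIF has no positive peak")
    if threshold_frac < 0:
        raise ValueError("threshold_frac must be >= 0")
    A = build_convolution_matrix(aif)
    pinv, _ = _truncated_pinv(A, threshold_frac)
    x = pinv @ ct.values
    cbf_si = max(float(x.max()), 0.0)
    return ConcCurve(x, ct.grid), cbf_si / CBF_TO_SI


def compute_cbv(ct: ConcCurve, aif: ConcCurve) -> float:
    """CBV (mL/100g) = 100 * ∫Ct / ∫Ca with trapezoid integrals."""
    if not ct.same_grid(aif):
        raise ValueError("tissue curve and AIF are on different grids")
    aif_area = aif.auc()
    if aif_area <= 0:
        raise ValueError("AIF integral must be positive")
    return max(100.0 * ct.auc() / aif_area, 0.0)


@dataclass
class PerfusionMaps:
    """CBF/CBV/MTT volumes plus the deconvolution provenance."""

    cbf: np.ndarray  # mL/100g/min
    cbv: np.ndarray  # mL/100g
    mtt: np.ndarray  # s
    svd_threshold: float
    aif_provenance: dict
    diagnostics: dict = field(default_factory=dict)


def perfusion_maps(conc: np.ndarray, aif: AifResult | ConcCurve,
                   mask: np.ndarray, threshold_frac: float = 0.2
                   ) -> PerfusionMaps:
    """Voxel-wise deconvolution of a 4-D concentration grid.

    The SVD of the AIF matrix is computed once and applied to all masked
    voxels; unmasked voxels stay zero.  Voxels whose curves are entirely
    non-positive yield zero maps and are counted in the diagnostics.
    """
    if isinstance(aif, AifResult):
        provenance = aif.to_jsonable()
        aif_curve = aif.aif
    else:
        provenance = {"method": "external", "metrics": None}
        aif_curve = aif
    conc = np.asarray(conc, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if conc.ndim != 4:
        raise ValueError("conc must be a 4-D (x, y, z, t) grid")
    if mask.shape != conc.shape[:3]:
        raise ValueError("mask shape does not match the volume")
    if not mask.any():
        raise ValueError("mask is empty")
    if conc.shape[-1] != aif_curve.grid.n:
        raise ValueError("concentration series length does not match the AIF grid")
    if aif_curve.values.max() <= 0:
        raise ValueError("AIF has no positive peak")

    A = build_convolution_matrix(aif_curve)
    pinv, svd_diag = _truncated_pinv(A, threshold_frac)
    aif_area = aif_curve.auc()
    if aif_area <= 0:
        raise ValueError("AIF integral must be positive")

    curves = conc[mask]  # (n_vox, t)
    X = curves @ pinv.T  # residue estimates per voxel
    cbf_si = np.clip(X.max(axis=1), 0.0, None)
    cbv_vals = np.clip(100.0 * np.trapezoid(curves, dx=aif_curve.grid.dt,
                                            axis=1) / aif_area, 0.0, None)
    cbf_vals = cbf_si / CBF_TO_SI
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt_vals = np.where(cbf_si > FLOW_EPSILON_SI,
                            60.0 * cbv_vals / cbf_vals, 0.0)

    shape = conc.shape[:3]
    cbf = np.zeros(shape)
    cbv = np.zeros(shape)
    mtt = np.zeros(shape)
    cbf[mask] = cbf_vals
    cbv[mask] = cbv_vals
    mtt[mask] = mtt_vals

    diagnostics = {
        "n_voxels": int(mask.sum()),
        "n_zero_flow": int((cbf_si <= FLOW_EPSILON_SI).sum()),
        "svd": svd_diag,
    }
    return PerfusionMaps(cbf=cbf, cbv=cbv, mtt=mtt,
                         svd_threshold=threshold_frac,
                         aif_provenance=provenance,
                         diagnostics=diagnostics)
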