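"""Automatic arterial-input-function determination on 4-D DSC data.

The chain mirrors the standard automatic-AIF workflow: convert signal to
concentration (data transformation), discard implausible voxels by simple
noise rules, normalize the survivors to unit area (data normalization),
cluster the normalized shapes with K-means or fuzzy C-means, score each
cluster's mean raw curve by peak / (TTP * FWHM) — high, early and narrow
is arterial — and return the mean raw curve of the winning cluster as the
AIF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from adsev.clustering import fcm, kmeans
from adsev.dsc_phantom import AcquisitionParams, ConcCurve, TimeGrid

__all__ = [
    "CandidateRules", "CandidateSet", "AifResult",
    "signal_to_concentration", "preselect_candidates", "select_aif",
    "aif_metrics",
]


def signal_to_concentration(signal: np.ndarray, acq: AcquisitionParams
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Invert the DSC signal model per voxel.

    C(t) = -ln(S(t)/S0_hat) / (kappa * te) with S0_hat the per-voxel mean
    of the first ``n_baseline`` samples.  Returns ``(conc, valid)`` where
    ``valid`` marks voxels with strictly positive signal throughout (a
    non-positive sample invalidates the voxel).  Negative concentrations
    (noise) are preserved for downstream filtering.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 4:
        raise ValueError("signal must be a 4-D (x, y, z, t) grid")
    if acq.n_baseline >= signal.shape[-1]:
        raise ValueError("n_baseline must be smaller than the series length")
    s0_hat = signal[..., : acq.n_baseline].mean(axis=-1)
    valid = (signal > 0).all(axis=-1) & (s0_hat > 0)
    conc = np.zeros_like(signal)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = signal[valid] / s0_hat[valid][..., None]
        conc[valid] = -np.log(ratio) / (acq.kappa * acq.te)
    return conc, valid


@dataclass(frozen=True)
class CandidateRules:
    """Voxel pre-selection thresholds.

    ``auc_percentile``: keep voxels whose raw-curve area is at or above
    this percentile of all valid voxels.  ``ttp_max_frac``: time-to-peak
    must not exceed this fraction of the acquisition window.
    ``max_neg_frac``: maximum tolerated fraction of negative samples,
    where "negative" means below ``-neg_sigma_mult`` times a per-voxel
    robust noise scale (median absolute first difference / (0.6745*sqrt(2))).
    The noise scale is zero on noise-free data, so the rule then counts
    strictly negative samples; without the scale, mean-zero noise would
    mark half of every voxel's pre-bolus baseline negative and reject
    even perfect arterial curves.
    """

    auc_percentile: float = 90.0
    ttp_max_frac: float = 0.5
    max_neg_frac: float = 0.2
    neg_sigma_mult: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.auc_percentile <= 100:
            raise ValueError("auc_percentile must lie in [0, 100]")
        if not 0 < self.ttp_max_frac <= 1:
            raise ValueError("ttp_max_frac must lie in (0, 1]")
        if not 0 <= self.max_neg_frac <= 1:
            raise ValueError("max_neg_frac must lie in [0, 1]")
        if self.neg_sigma_mult < 0:
            raise ValueError("neg_sigma_mult must be >= 0")


@dataclass
class CandidateSet:
    """Surviving AIF candidate voxels with unit-area normalized shapes."""

    indices: np.ndarray  # (n, 3) voxel coordinates
    curves_norm: np.ndarray  # (n, t) unit-AUC shapes used for clustering
    curves_raw: np.ndarray  # (n, t) raw concentration curves
    grid: TimeGrid
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.indices.shape[0]


def preselect_candidates(conc: np.ndarray, grid: TimeGrid,
                         rules: CandidateRules | None = None,
                         valid: np.ndarray | None = None,
                         min_candidates: int = 10) -> CandidateSet:
    """Apply the noise-removal rules and normalize survivors to unit area.

    All rules are evaluated as independent predicates on the full valid
    voxel set and intersected, so the outcome does not depend on rule
    order.  Raises with the per-rule removal counts if fewer than
    ``min_candidates`` voxels survive.
    """
    rules = rules or CandidateRules()
    conc = np.asarray(conc, dtype=float)
    if conc.ndim != 4 or conc.shape[-1] != grid.n:
        raise ValueError("conc must be (x, y, z, t) matching the grid")
    if valid is None:
        valid = np.isfinite(conc).all(axis=-1)

    flat = conc.reshape(-1, grid.n)
    valid_flat = valid.ravel()

    aucs = np.trapezoid(flat, dx=grid.dt, axis=-1)
    ttp = np.argmax(flat, axis=-1) * grid.dt
    # robust per-voxel noise scale; exactly 0 for noise-free smooth curves
    sigma_hat = (np.median(np.abs(np.diff(flat, axis=-1)), axis=-1)
                 * 1.4826 / np.sqrt(2.0))
    neg_floor = -rules.neg_sigma_mult * sigma_hat
    neg_frac = (flat < neg_floor[:, None]).mean(axis=-1)

    if valid_flat.any():
        auc_thresh = float(np.percentile(aucs[valid_flat],
                                         rules.auc_percentile))
    else:
        auc_thresh = np.inf
    ttp_max = rules.ttp_max_frac * grid.duration

    pass_auc = aucs >= auc_thresh
    pass_auc &= aucs > 0  # unit-area normalization needs positive area
    pass_ttp = ttp <= ttp_max
    pass_neg = neg_frac <= rules.max_neg_frac
    keep = valid_flat & pass_auc & pass_ttp & pass_neg

    diagnostics = {
        "n_voxels": int(flat.shape[0]),
        "n_valid": int(valid_flat.sum()),
        "auc_threshold": auc_thresh,
        "removed_invalid": int((~valid_flat).sum()),
        "removed_by_auc": int((valid_flat & ~pass_auc).sum()),
        "removed_by_ttp": int((valid_flat & ~pass_ttp).sum()),
        "removed_by_neg_frac": int((valid_flat & ~pass_neg).sum()),
        "n_kept": int(keep.sum()),
        "rules": rules,
    }
    if keep.sum() < min_candidates:
        raise ValueError(
            f"only {int(keep.sum())} candidate voxels survive "
            f"(need >= {min_candidates}); removal counts: "
            f"invalid={diagnostics['removed_invalid']}, "
            f"auc={diagnostics['removed_by_auc']}, "
            f"ttp={diagnostics['removed_by_ttp']}, "
            f"neg={diagnostics['removed_by_neg_frac']} — relax the rules"
        )

    kept_idx = np.nonzero(keep)[0]
    raw = flat[kept_idx]
    norm = raw / aucs[kept_idx][:, None]
    indices = np.stack(np.unravel_index(kept_idx, conc.shape[:3]), axis=1)
    return CandidateSet(indices=indices, curves_norm=norm, curves_raw=raw,
                        grid=grid, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# AIF metrics and cluster scoring


def _fwhm(values: np.ndarray, dt: float) -> float:
    """Full width at half maximum by linear interpolation between samples.

    Raises if the curve does not fall below half maximum on both sides of
    the peak (no measurable width).
    """
    peak_idx = int(np.argmax(values))
    half = values[peak_idx] / 2.0

    left = None
    for i in range(peak_idx, 0, -1):
        if values[i - 1] < half <= values[i]:
            frac = (half - values[i - 1]) / (values[i] - values[i - 1])
            left = (i - 1 + frac) * dt
            break
    right = None
    for i in range(peak_idx, len(values) - 1):
        if values[i + 1] < half <= values[i]:
            frac = (values[i] - half) / (values[i] - values[i + 1])
            right = (i + frac) * dt
            break
    if left is None or right is None:
        raise ValueError("curve does not cross half maximum on both sides")
    return right - left


def aif_metrics(curve: ConcCurve) -> dict:
    """Peak, time-to-peak (s), trapezoid AUC (conc*s) and FWHM (s).

    All four must come out finite and positive; a curve without a positive
    maximum, with its peak at t = 0, or never crossing half maximum is
    rejected.
    """
    values = curve.values
    peak = float(values.max())
    if peak <= 0:
        raise ValueError("curve has no positive maximum")
    dt = curve.grid.dt
    ttp = float(np.argmax(values)) * dt
    if ttp <= 0:
        raise ValueError("time-to-peak is not positive (peak at t = 0)")
    auc = float(np.trapezoid(values, dx=dt))
    fwhm = _fwhm(values, dt)
    if auc <= 0:
        raise ValueError("curve area is not positive")
    return {"peak": peak, "ttp": ttp, "auc": auc, "fwhm": fwhm}


@dataclass
class AifResult:
    """Selected AIF: mean of the raw curves in the winning cluster."""

    aif: ConcCurve
    cluster_id: int
    member_indices: np.ndarray  # (n_members, 3) voxel coordinates
    metrics: dict  # peak, ttp, auc, fwhm of the selected curve
    method: str
    seed: int
    cluster_scores: np.ndarray | None = None

    def to_jsonable(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "n_members": int(self.member_indices.shape[0]),
            "metrics": self.metrics,
            "method": self.method,
            "seed": self.seed,
        }


def _smooth(values: np.ndarray, dt: float, window_s: float = 1.0) -> np.ndarray:
    """Moving average over ~window_s; no-op when dt >= window_s."""
    w = max(int(round(window_s / dt)), 1)
    if w == 1:
        return values
    kernel = np.ones(w) / w
    return np.convolve(values, kernel, mode="same")


def _cluster_score(mean_raw: np.ndarray, grid: TimeGrid) -> float:
    """peak / (TTP * FWHM): high, early, narrow wins; unmeasurable -> -inf.

    Metrics for scoring are taken on a 1-s moving-average copy of the
    curve: on a raw noisy mean (especially of a small cluster) the
    half-maximum width of the single highest noise sample can be
    arbitrarily small, which would let a flat tissue cluster outscore a
    genuine bolus.  The smoothing affects only the ranking, never the
    returned AIF or its reported metrics.
    """
    try:
        m = aif_metrics(ConcCurve(_smooth(mean_raw, grid.dt), grid))
    except ValueError:
        return -math.inf
    return m["peak"] / (m["ttp"] * m["fwhm"])


def select_aif(candidates: CandidateSet, method: str = "kmeans",
               k: int = 5, seed: int = 0, **cluster_kwargs) -> AifResult:
    """Cluster the normalized candidate shapes and pick the arterial cluster.

    The FCM membership matrix is hardened by argmax (ties to the lower
    cluster index) before averaging.  Each cluster's mean *raw* curve is
    scored by peak/(TTP*FWHM); degenerate clusters (empty, flat, or not
    crossing half maximum) score -inf and cannot be selected.
    """
    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    if method == "kmeans":
        result = kmeans(candidates.curves_norm, k, seed=seed, **cluster_kwargs)
    elif method == "fcm":
        result = fcm(candidates.curves_norm, k, seed=seed, **cluster_kwargs)
    else:
        raise ValueError(f"unknown method {method!r} (expected kmeans|fcm)")

    labels = result.labels
    scores = np.full(k, -math.inf)
    means = np.zeros((k, candidates.grid.n))
    for c in range(k):
        members = labels == c
        if not members.any():
            continue
        means[c] = candidates.curves_raw[members].mean(axis=0)
        scores[c] = _cluster_score(means[c], candidates.grid)
    if not np.isfinite(scores).any():
        raise ValueError("no cluster has a measurable bolus shape")
    best = int(np.argmax(scores))  # ties -> lower cluster index
    aif = ConcCurve(means[best], candidates.grid)
    return AifResult(
        aif=aif, cluster_id=best,
        member_indices=candidates.indices[labels == best],
        metrics=aif_metrics(aif), method=method, seed=seed,
        cluster_scores=scores,
    )
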