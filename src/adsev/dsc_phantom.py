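"""Forward tracer-kinetics model and seeded 4-D DSC-MRI phantom generator.

The phantom implements the standard bolus-tracking chain:

* arterial input function (AIF) as a gamma-variate bolus
  ``Ca(t) = a (t - t0)^r exp(-(t - t0)/b)`` for ``t > t0``;
* tissue response by the indicator-dilution convolution
  ``Ct(t) = F_si * (Ca ⊛ R)(t)`` with residue function ``R`` (exponential
  or boxcar), where ``F_si = CBF / 6000`` converts mL/100g/min to 1/s at
  unit tissue density;
* gradient-echo DSC signal ``S(t) = S0 exp(-kappa * TE * C(t))`` with
  optional additive Gaussian noise.

Partial-volume voxels mix arterial and tissue concentration linearly
(``C = pv * Ca + (1 - pv) * Ct``) before conversion to signal.  All
randomness flows from a single integer seed, so phantoms are
bit-reproducible.

Units: CBF in mL/100g/min, CBV in mL/100g, MTT in s, time in s,
concentration in arbitrary mM-like units; tissue density is 1 g/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TimeGrid", "ConcCurve", "GammaVariateParams", "TissueParams",
    "AcquisitionParams", "RegionSpec", "PhantomSpec", "Phantom",
    "gamma_variate", "residue_function", "tissue_concentration",
    "concentration_to_signal", "generate_phantom",
    "default_grid", "default_acquisition", "default_phantom_spec",
    "gamma_amplitude_for_peak",
]

#: mL/100g/min -> 1/s at density 1 g/mL (divide by 100 g, by 60 s/min)
CBF_TO_SI = 1.0 / 6000.0


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid starting at t = 0."""

    dt: float
    n: int

    def __post_init__(self) -> None:
        _require_finite("TimeGrid.dt", self.dt)
        if self.dt <= 0:
            raise ValueError(f"TimeGrid.dt must be > 0, got {self.dt}")
        if self.n < 8:
            raise ValueError(f"TimeGrid.n must be >= 8, got {self.n}")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    @property
    def duration(self) -> float:
        """Length of the acquisition window, (n - 1) * dt."""
        return (self.n - 1) * self.dt


@dataclass(frozen=True)
class ConcCurve:
    """A concentration time-series on a uniform :class:`TimeGrid`."""

    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.shape[0] != self.grid.n:
            raise ValueError(
                f"curve length {values.shape} does not match grid n={self.grid.n}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("curve contains non-finite samples")
        object.__setattr__(self, "values", values)

    def same_grid(self, other: "ConcCurve") -> bool:
        return self.grid == other.grid

    def auc(self) -> float:
        """Trapezoid area under the curve (conc * s)."""
        return float(np.trapezoid(self.values, dx=self.grid.dt))


@dataclass(frozen=True)
class GammaVariateParams:
    """Gamma-variate bolus: t0 arrival (s), a amplitude, r shape, b scale (s)."""

    t0: float
    a: float
    r: float
    b: float

    def __post_init__(self) -> None:
        _require_finite("GammaVariateParams", self.t0, self.a, self.r, self.b)
        if self.a <= 0 or self.r <= 0 or self.b <= 0 or self.t0 < 0:
            raise ValueError(
                "require a > 0, r > 0, b > 0, t0 >= 0; got "
                f"a={self.a}, r={self.r}, b={self.b}, t0={self.t0}"
            )

    @property
    def time_to_peak(self) -> float:
        """Analytic mode of the bolus, t0 + r*b."""
        return self.t0 + self.r * self.b

    @property
    def peak_value(self) -> float:
        return self.a * (self.r * self.b) ** self.r * math.exp(-self.r)


def gamma_amplitude_for_peak(peak: float, r: float, b: float) -> float:
    """Amplitude ``a`` such that the gamma-variate mode equals ``peak``."""
    if peak <= 0:
        raise ValueError("peak must be > 0")
    return peak / ((r * b) ** r * math.exp(-r))


@dataclass(frozen=True)
class TissueParams:
    """Hemodynamics of one tissue compartment.

    ``pv_arterial`` is the arterial signal fraction mixed into the voxel;
    1.0 means a pure arterial voxel.  The central-volume theorem
    MTT = (CBV/CBF)*60 is enforced at construction (within 1e-9) whenever
    CBF > 0.
    """

    cbf: float  # mL/100g/min
    cbv: float  # mL/100g
    mtt: float  # s
    delay: float = 0.0  # s
    pv_arterial: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("TissueParams", self.cbf, self.cbv, self.mtt,
                        self.delay, self.pv_arterial)
        if self.cbf < 0 or self.cbv < 0:
            raise ValueError("cbf and cbv must be >= 0")
        if not 0.0 <= self.pv_arterial <= 1.0:
            raise ValueError("pv_arterial must lie in [0, 1]")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.cbf > 0:
            if self.mtt <= 0:
                raise ValueError("mtt must be > 0 when cbf > 0")
            expected = (self.cbv / self.cbf) * 60.0
            if abs(self.mtt - expected) > 1e-9:
                raise ValueError(
                    f"central-volume violation: mtt={self.mtt} but "
                    f"(cbv/cbf)*60={expected}"
                )

    @classmethod
    def from_cbf_cbv(cls, cbf: float, cbv: float, *, delay: float = 0.0,
                     pv_arterial: float = 0.0) -> "TissueParams":
        """Build consistent parameters, deriving MTT from the central-volume theorem."""
        mtt = (cbv / cbf) * 60.0 if cbf > 0 else 1.0
        return cls(cbf=cbf, cbv=cbv, mtt=mtt, delay=delay,
                   pv_arterial=pv_arterial)


@dataclass(frozen=True)
class AcquisitionParams:
    """DSC signal model parameters (echo time, baseline, susceptibility, noise)."""

    te: float = 0.03  # s
    s0: float = 100.0
    kappa: float = 5.0  # 1/(mM*s)
    n_baseline: int = 8
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("AcquisitionParams", self.te, self.s0, self.kappa,
                        self.noise_sigma)
        if self.te <= 0 or self.s0 <= 0 or self.kappa <= 0:
            raise ValueError("require te > 0, s0 > 0, kappa > 0")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned box region painted into the phantom volume.

    Regions are painted in list order, later boxes overwriting earlier
    ones; ``tissue=None`` marks background (no tracer).  Bounds are
    half-open voxel index ranges.
    """

    name: str
    box: tuple[int, int, int, int, int, int]  # x0, x1, y0, y1, z0, z1
    tissue: TissueParams | None


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry plus ground-truth physiology of a phantom."""

    shape: tuple[int, int, int]
    aif_params: GammaVariateParams
    regions: tuple[RegionSpec, ...]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if not self.regions:
            raise ValueError("at least one region required")
        x0, x1, y0, y1, z0, z1 = self.regions[0].box
        nx, ny, nz = self.shape
        if (x0, y0, z0) != (0, 0, 0) or (x1, y1, z1) != (nx, ny, nz):
            raise ValueError("first region must cover the whole volume")
        if not any(r.tissue is not None and r.tissue.pv_arterial == 1.0
                   for r in self.regions):
            raise ValueError(
                "phantom spec must contain at least one pure arterial region "
                "(pv_arterial == 1)"
            )

    def label_volume(self) -> np.ndarray:
        """Region index per voxel, painted in declaration order."""
        labels = np.zeros(self.shape, dtype=np.int16)
        for idx, region in enumerate(self.regions):
            x0, x1, y0, y1, z0, z1 = region.box
            labels[x0:x1, y0:y1, z0:z1] = idx
        return labels


@dataclass(frozen=True)
class Phantom:
    """4-D DSC signal plus the ground truth it was generated from."""

    signal: np.ndarray  # (x, y, z, t)
    region_mask: np.ndarray  # (x, y, z) region index
    cbf: np.ndarray  # truth maps
    cbv: np.ndarray
    mtt: np.ndarray
    true_aif: ConcCurve
    seed: int
    spec: PhantomSpec
    acq: AcquisitionParams
    grid: TimeGrid

    def region_indices(self, name: str) -> np.ndarray:
        """Boolean voxel mask of the named region."""
        idx = [i for i, r in enumerate(self.spec.regions) if r.name == name]
        if not idx:
            raise KeyError(f"no region named {name!r}")
        return np.isin(self.region_mask, idx)

    def tissue_mask(self) -> np.ndarray:
        """Voxels with any tracer (non-background)."""
        bg = [i for i, r in enumerate(self.spec.regions) if r.tissue is None]
        return ~np.isin(self.region_mask, bg)


# ---------------------------------------------------------------------------
# forward model operations


def gamma_variate(params: GammaVariateParams, grid: TimeGrid) -> ConcCurve:
    """Evaluate the gamma-variate bolus on the grid; zero for t <= t0."""
    tau = grid.t - params.t0
    with np.errstate(invalid="ignore"):
        values = np.where(
            tau > 0,
            params.a * np.power(np.clip(tau, 0, None), params.r)
            * np.exp(-np.clip(tau, 0, None) / params.b),
            0.0,
        )
    return ConcCurve(values, grid)


def residue_function(mtt: float, grid: TimeGrid,
                     model: str = "exponential") -> ConcCurve:
    """Residue function R(t): fraction of tracer remaining at time t.

    ``exponential`` gives R(t) = exp(-t/mtt); ``boxcar`` gives R = 1 for
    t < mtt and 0 after (plug flow).  Both satisfy R(0) = 1, R
    non-increasing, and integral mtt (in the continuum limit).
    """
    if not math.isfinite(mtt) or mtt <= 0:
        raise ValueError(f"mtt must be > 0, got {mtt}")
    t = grid.t
    if model == "exponential":
        values = np.exp(-t / mtt)
    elif model == "boxcar":
        values = (t < mtt).astype(float)
    else:
        raise ValueError(f"unknown residue model {model!r}")
    return ConcCurve(values, grid)


def _shift_curve(values: np.ndarray, grid: TimeGrid, delay: float) -> np.ndarray:
    """Shift a curve later in time by ``delay`` with zero fill before onset."""
    if delay == 0:
        return values
    return np.interp(grid.t - delay, grid.t, values, left=0.0, right=values[-1])


def tissue_concentration(aif: ConcCurve, tissue: TissueParams,
                         grid: TimeGrid,
                         residue_model: str = "exponential") -> ConcCurve:
    """Forward convolution Ct(t_i) = F_si * sum_{j<=i} Ca(t_j - delay) R(t_i - t_j) dt."""
    if aif.grid != grid:
        raise ValueError("AIF grid does not match the requested grid")
    if tissue.cbf == 0:
        return ConcCurve(np.zeros(grid.n), grid)
    cbf_si = tissue.cbf * CBF_TO_SI
    ca = _shift_curve(aif.values, grid, tissue.delay)
    r = residue_function(tissue.mtt, grid, residue_model).values
    ct = cbf_si * grid.dt * np.convolve(ca, r)[: grid.n]
    return ConcCurve(np.clip(ct, 0.0, None), grid)


def concentration_to_signal(c: ConcCurve | np.ndarray,
                            acq: AcquisitionParams) -> np.ndarray:
    """DSC signal S(t) = s0 * exp(-kappa * te * C(t)); array in, array out."""
    values = c.values if isinstance(c, ConcCurve) else np.asarray(c, float)
    if np.any(values < 0):
        raise ValueError("concentration must be >= 0")
    return acq.s0 * np.exp(-acq.kappa * acq.te * values)


# ---------------------------------------------------------------------------
# defaults and phantom generation


def default_grid() -> TimeGrid:
    """60 s window sampled at 0.1 s (fine enough for <2% quadrature bias)."""
    return TimeGrid(dt=0.1, n=600)


def default_acquisition(noise_sigma: float = 0.0) -> AcquisitionParams:
    return AcquisitionParams(te=0.03, s0=100.0, kappa=5.0, n_baseline=8,
                             noise_sigma=noise_sigma)


def default_phantom_spec(shape: tuple[int, int, int] = (32, 32, 4),
                         pv_fraction: float = 0.4) -> PhantomSpec:
    """32x32x4 phantom: background shell, gray/white halves, a central
    2x2 arterial column and a partial-volume shell around it.

    Gray matter: CBF 60 mL/100g/min, CBV 4 mL/100g (MTT 4 s); white
    matter: CBF 25, CBV 2 (MTT 4.8 s).  The AIF is a gamma variate with
    t0 = 10 s, r = 3, b = 1.5 s and amplitude scaled to peak 6.
    """
    nx, ny, nz = shape
    aif = GammaVariateParams(t0=10.0, a=gamma_amplitude_for_peak(6.0, 3.0, 1.5),
                             r=3.0, b=1.5)
    gray = TissueParams.from_cbf_cbv(60.0, 4.0)
    white = TissueParams.from_cbf_cbv(25.0, 2.0)
    artery = TissueParams(cbf=0.0, cbv=0.0, mtt=1.0, pv_arterial=1.0)
    pv = replace(gray, pv_arterial=pv_fraction)
    cx, cy = nx // 2, ny // 2
    regions = (
        RegionSpec("background", (0, nx, 0, ny, 0, nz), None),
        RegionSpec("gray", (2, nx // 2, 2, ny - 2, 0, nz), gray),
        RegionSpec("white", (nx // 2, nx - 2, 2, ny - 2, 0, nz), white),
        RegionSpec("pv_shell", (cx - 2, cx + 3, cy - 2, cy + 3, 0, nz), pv),
        RegionSpec("artery", (cx, cx + 2, cy, cy + 2, 0, nz), artery),
    )
    return PhantomSpec(shape=shape, aif_params=aif, regions=regions)


def generate_phantom(spec: PhantomSpec, acq: AcquisitionParams,
                     grid: TimeGrid, seed: int) -> Phantom:
    """Simulate the 4-D DSC signal with ground truth; bit-reproducible per seed."""
    labels = spec.label_volume()
    true_aif = gamma_variate(spec.aif_params, grid)

    nx, ny, nz = spec.shape
    signal = np.empty((nx, ny, nz, grid.n), dtype=float)
    cbf = np.zeros(spec.shape)
    cbv = np.zeros(spec.shape)
    mtt = np.zeros(spec.shape)

    for idx, region in enumerate(spec.regions):
        mask = labels == idx
        if not mask.any():
            continue
        tis = region.tissue
        if tis is None:
            conc = np.zeros(grid.n)
        else:
            ct = tissue_concentration(true_aif, tis, grid).values
            conc = tis.pv_arterial * true_aif.values + (1 - tis.pv_arterial) * ct
            cbf[mask] = tis.cbf
            cbv[mask] = tis.cbv
            mtt[mask] = tis.mtt if tis.cbf > 0 else 0.0
        signal[mask] = concentration_to_signal(conc, acq)

    if acq.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, acq.noise_sigma, size=signal.shape)
        signal = np.clip(signal, 0.0, None)

    return Phantom(signal=signal, region_mask=labels, cbf=cbf, cbv=cbv,
                   mtt=mtt, true_aif=true_aif, seed=seed, spec=spec,
                   acq=acq, grid=grid)
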