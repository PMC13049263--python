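"""Absolute metabolite quantification by phantom replacement.

Fitted amplitudes from a coil-combined main scan are corrected for partial
saturation (F = (1 − cosθ·E)/(sinθ·(1 − E)), E = e^{−TR/T1}) and scaled by
the same quantity measured on a reference phantom of known concentration:

    [m](r) = F_m(r)·Ŝ_m(r) / (F_P(r)·Ŝ_P(r)) · [P]

Because identical coil weights are applied to the reference and main scans,
every fixed per-voxel scaling (receive gain, the WSVD normalization choice)
cancels in the ratio.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from . import constants
from .calibration import CoilWeights, TransmitMap, combine_channels
from .containers import SpectralStack
from .fitting import FitResult, PriorKnowledge, fit_fid
from .grids import GridGeometry
from .synthetic import ProtocolParams, flip_angle_rad

log = logging.getLogger(__name__)


@dataclass
class SaturationTable:
    """Metabolite T1s, TR and the per-voxel flip map for Eq.-style partial-
    saturation correction."""

    t1_s: Dict[str, float]
    tr_s: float
    flip_map_rad: np.ndarray      # (nx,ny,nz), radians

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        for m, t1 in self.t1_s.items():
            if t1 <= 0:
                raise ValueError(f"T1 for {m!r} must be positive")

    @classmethod
    def from_transmit(cls, transmit: TransmitMap, protocol: ProtocolParams,
                      t1_s: Optional[Dict[str, float]] = None
                      ) -> "SaturationTable":
        theta = flip_angle_rad(transmit.b1_plus, protocol.voltages_v[0],
                               protocol)
        return cls(t1_s=dict(t1_s or constants.T1_LITERATURE_S),
                   tr_s=protocol.tr_s, flip_map_rad=theta)


@dataclass
class ReferencePhantomSpec:
    """Reference phantom: compound, concentration [P], T1, and the fitted
    per-voxel amplitude map Ŝ_P(r) from the matched reference scan."""

    compound: str
    concentration_mol_per_l: float
    t1_s: float
    fitted_amplitude_map: np.ndarray

    def __post_init__(self):
        if self.concentration_mol_per_l <= 0:
            raise ValueError("reference concentration must be positive")
        if self.t1_s <= 0:
            raise ValueError("reference T1 must be positive")


@dataclass
class ConcentrationMap:
    """Absolute concentrations (mol/L) with CRLB%s and quality masks."""

    values: Dict[str, np.ndarray]
    crlb_percent: Dict[str, np.ndarray]
    ratio_crlb_percent: np.ndarray
    mask1: np.ndarray
    mask2: np.ndarray
    grid: GridGeometry
    meta: dict = field(default_factory=dict)


@dataclass
class IRSeries:
    """Inversion-recovery signal-vs-TI series."""

    ti_s: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        self.ti_s = np.asarray(self.ti_s, float)
        self.signals = np.asarray(self.signals, float)
        if self.ti_s.size != self.signals.size:
            raise ValueError("ti_s and signals must have equal length")
        if self.ti_s.size > 1 and np.any(np.diff(self.ti_s) <= 0):
            raise ValueError("inversion times must be strictly increasing")


def saturation_factor(theta_rad, tr_s: float, t1_s: float):
    """Partial-saturation correction F = (1 − cosθ·E)/(sinθ·(1 − E)) for a
    spoiled steady-state sequence; multiplies a measured amplitude to undo
    the saturation attenuation. θ must lie in (0, π)."""
    theta = np.asarray(theta_rad, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= np.pi):
        raise ValueError("flip angle must lie in (0, pi)")
    if tr_s <= 0 or t1_s <= 0:
        raise ValueError("tr_s and t1_s must be positive")
    e = np.exp(-tr_s / t1_s)
    out = (1.0 - np.cos(theta) * e) / (np.sin(theta) * (1.0 - e))
    return float(out) if np.isscalar(theta_rad) else out


def absolute_concentration(s_m, s_p, f_m, f_p, p_conc: float):
    """Phantom-replacement concentration [m] = F_m·Ŝ_m/(F_P·Ŝ_P)·[P]."""
    s_p = np.asarray(s_p, float)
    if np.any(s_p == 0) or np.any(np.asarray(f_p) == 0):
        raise ValueError("reference amplitude/saturation factor must be nonzero")
    out = np.asarray(f_m, float) * np.asarray(s_m, float) / (
        np.asarray(f_p, float) * s_p) * p_conc
    return float(out) if out.ndim == 0 else out


def ratio_crlb_percent(fit: FitResult, num: str = "Lac",
                       other: str = "Glx") -> float:
    """Delta-method CRLB% of the ratio R = a_num/(a_num + a_other).

    Propagates the amplitude covariance from the Fisher information through
    the first-order expansion of R; returns 100·sd(R)/R (+∞ when R or the
    denominator vanishes or the covariance is unavailable).
    """
    a_l = fit.amplitude(num)
    a_g = fit.amplitude(other)
    s = a_l + a_g
    if s == 0 or a_l == 0:
        return np.inf
    cov = fit.amplitude_covariance([num, other])
    if not np.all(np.isfinite(cov)):
        return np.inf
    grad = np.array([a_g / s ** 2, -a_l / s ** 2])
    var = float(grad @ cov @ grad)
    if var < 0:
        return np.inf
    r = a_l / s
    return 100.0 * np.sqrt(var) / r


def apply_masks(hdo_mol_l: np.ndarray, hdo_crlb_percent: np.ndarray,
                ratio_crlb_pct: np.ndarray,
                hdo_min_mol_l: float = constants.MASK_HDO_MIN_MOL_L,
                hdo_crlb_max: float = constants.MASK_HDO_CRLB_MAX_PERCENT,
                ratio_crlb_max: float = constants.MASK_RATIO_CRLB_MAX_PERCENT,
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Quality-control masks.

    Mask #1 keeps voxels with [HDO] ≥ 5 mmol/L and HDO CRLB ≤ 30%; mask #2
    additionally requires the Lac/(Lac+Glx) ratio CRLB ≤ 30%. mask2 ⊆ mask1.
    """
    hdo = np.asarray(hdo_mol_l, float)
    c1 = np.asarray(hdo_crlb_percent, float)
    c2 = np.asarray(ratio_crlb_pct, float)
    mask1 = (hdo >= hdo_min_mol_l) & (c1 <= hdo_crlb_max)
    mask2 = mask1 & (c2 <= ratio_crlb_max)
    return mask1, mask2


def fit_reference_amplitudes(ref_stack: SpectralStack, weights: CoilWeights,
                             prior: PriorKnowledge, metabolite: str = "HDO",
                             mask: Optional[np.ndarray] = None
                             ) -> np.ndarray:
    """Per-voxel fitted amplitude map Ŝ_P(r) of the reference compound from
    the coil-combined reference scan."""
    combined = combine_channels(ref_stack, weights)
    shape = combined.shape[:3]
    amp = np.zeros(shape)
    if mask is None:
        mask = weights.valid
    for ix, iy, iz in np.argwhere(mask):
        try:
            fit = fit_fid(combined[ix, iy, iz], ref_stack.dwell_s, prior)
        except ValueError:
            continue
        if fit.converged:
            amp[ix, iy, iz] = fit.amplitude(metabolite)
    return amp


def quantify_scan(main_stack: SpectralStack, weights: CoilWeights,
                  transmit: TransmitMap, prior: PriorKnowledge,
                  sat: SaturationTable, ref: ReferencePhantomSpec,
                  mask: Optional[np.ndarray] = None,
                  prefit: Optional[Dict[tuple, FitResult]] = None,
                  prior_map: Optional[Dict[tuple, PriorKnowledge]] = None,
                  ) -> ConcentrationMap:
    """Quantify one main-scan acquisition into absolute concentration maps.

    Per voxel: combine channels with the calibrated weights, fit the
    prior-knowledge Lorentzian model, saturation-correct each metabolite
    amplitude with its per-voxel flip angle, and apply phantom replacement
    against the reference amplitude map. CRLB%s propagate into the masks.

    ``prefit`` optionally collects the per-voxel :class:`FitResult` objects
    (keyed by voxel index) for reuse, e.g. linewidth fixing.
    """
    if main_stack.grid != weights.grid or main_stack.grid != transmit.grid:
        raise ValueError("main scan and calibration grids must match")
    combined = combine_channels(main_stack, weights)
    shape = combined.shape[:3]
    mets = [p.name for p in prior.peaks]
    values = {m: np.zeros(shape) for m in mets}
    crlb = {m: np.full(shape, np.inf) for m in mets}
    ratio_pct = np.full(shape, np.inf)

    if mask is None:
        mask = weights.valid & transmit.valid_mask
    else:
        mask = mask & weights.valid & transmit.valid_mask
    usable = mask & (ref.fitted_amplitude_map != 0)

    f_p = np.ones(shape)
    inrange = (sat.flip_map_rad > 0) & (sat.flip_map_rad < np.pi)
    usable &= inrange
    f_p[inrange] = saturation_factor(sat.flip_map_rad[inrange], sat.tr_s,
                                     ref.t1_s)

    have_lac_glx = "Lac" in mets and "Glx" in mets
    for ix, iy, iz in np.argwhere(usable):
        prior_v = prior
        if prior_map is not None:
            prior_v = prior_map.get((ix, iy, iz), prior)
        try:
            fit = fit_fid(combined[ix, iy, iz], main_stack.dwell_s, prior_v)
        except ValueError:
            continue
        if prefit is not None:
            prefit[(ix, iy, iz)] = fit
        if not fit.converged:
            continue
        theta = sat.flip_map_rad[ix, iy, iz]
        s_p = ref.fitted_amplitude_map[ix, iy, iz]
        for m in mets:
            if m not in sat.t1_s:
                continue
            f_m = saturation_factor(theta, sat.tr_s, sat.t1_s[m])
            values[m][ix, iy, iz] = absolute_concentration(
                fit.amplitude(m), abs(s_p), f_m, f_p[ix, iy, iz],
                ref.concentration_mol_per_l)
            crlb[m][ix, iy, iz] = fit.crlb_percent_amplitude.get(m, np.inf)
        if have_lac_glx:
            ratio_pct[ix, iy, iz] = ratio_crlb_percent(fit)

    hdo_key = "HDO" if "HDO" in mets else mets[0]
    mask1, mask2 = apply_masks(values[hdo_key], crlb[hdo_key], ratio_pct)
    mask1 &= usable
    mask2 &= usable
    if not have_lac_glx:
        mask2 = mask1.copy()
    retained = mask1.sum()
    if retained:
        log.info("mask1 kept %d voxels; mask2 discarded %.0f%% of them",
                 retained, 100.0 * (1 - mask2.sum() / retained))
    return ConcentrationMap(values=values, crlb_percent=crlb,
                            ratio_crlb_percent=ratio_pct,
                            mask1=mask1, mask2=mask2, grid=main_stack.grid,
                            meta={"reference": ref.compound,
                                  "p_conc_mol_l": ref.concentration_mol_per_l})


def fit_t1_inversion_recovery(series: IRSeries
                              ) -> Tuple[float, float, float, float, bool]:
    """Three-parameter inversion-recovery fit S(TI) = a·(1 − b·e^{−TI/T1}).

    ``b`` is free to absorb imperfect inversion (b = 2 for perfect).
    Returns (t1_s, a, b, residual_norm, converged); an unidentifiable
    series (e.g. constant signal) is flagged unconverged.
    """
    ti, y = series.ti_s, series.signals
    if ti.size < 4:
        raise ValueError("need at least 4 inversion times")
    if np.ptp(y) == 0:
        return np.nan, float(y[0]) if y.size else np.nan, 0.0, 0.0, False

    a0 = float(y[-1]) if y[-1] != 0 else float(np.max(np.abs(y)) or 1.0)
    # crude T1 init: TI of the signal nearest zero is ~ T1·ln 2
    t1_0 = float(ti[np.argmin(np.abs(y))] / np.log(2.0)) or float(np.median(ti))
    t1_0 = min(max(t1_0, ti[0] / 10.0), ti[-1] * 10.0)

    def residuals(p):
        a, b, t1 = p
        return a * (1.0 - b * np.exp(-ti / t1)) - y

    sol = least_squares(residuals, np.array([a0, 2.0, t1_0]),
                        bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    a, b, t1 = sol.x
    return float(t1), float(a), float(b), float(np.linalg.norm(sol.fun)), bool(sol.success)


def natural_abundance_hdo(deuterium_fraction: float,
                          brain_water_fraction: float) -> float:
    """Expected natural-abundance HDO deuteron concentration in brain,
    mmol/L: hydrogen-site molarity of pure water (2 × 55.5 mol/L) × the
    deuterium fraction of water × the tissue water fraction."""
    for f in (deuterium_fraction, brain_water_fraction):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    mol_l = (constants.WATER_H_SITE_MOLARITY * deuterium_fraction
             * brain_water_fraction)
    return mol_l * 1e3


def d2o_recipe_deuteron_concentration(mass_g: float, volume_l: float) -> float:
    """Deuteron molarity (mol/L) of a D2O spike: two deuterons per molecule
    of D2O (20.028 g/mol) dissolved in ``volume_l`` litres."""
    if mass_g < 0:
        raise ValueError("mass_g must be non-negative")
    if volume_l <= 0:
        raise ValueError("volume_l must be positive")
    return (mass_g / constants.D2O_MOLAR_MASS_G_PER_MOL
            * constants.D2O_DEUTERONS_PER_MOLECULE / volume_l)
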