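"""Synthetic multi-coil CSI data with known ground truth.

Emulates the statistical structure the quantification pipeline assumes:
spatially smooth transmit (B1+) and complex per-channel receive (B1−)
fields, four Lorentzian deuterium resonances (HDO, Glc, Glx, Lac), complex
Gaussian channel noise correlated across channels through a full covariance
Ξ, a multi-voltage excitation series for variable-flip-angle calibration,
and linear post-ingestion concentration trajectories with region-specific
rates. Every downstream stage is tested against these known answers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import constants
from .containers import SpectralStack
from .grids import GridGeometry

log = logging.getLogger(__name__)

#: Region label codes used by the scenario builders.
LABELS = {
    "background": 0,
    "bath": 1, "lac_ball": 2, "fum_ball": 3,
    "brain": 1, "tumor": 2,
}

#: Fumarate deuteron chemical shift (ppm); the vinyl deuterons of fumarate.
FUM_SHIFT_PPM = 6.5

#: Default region-specific linear production rates, μmol/L/min.
#: Lac rises fastest in tumor; Glx labeling is fastest in healthy brain.
DEFAULT_RATES: Dict[str, Dict[str, float]] = {
    "tumor":   {"Lac": 2.3, "Glx": 3.8, "HDO": 30.0, "Glc": 8.0},
    "nawm":    {"Lac": 1.0, "Glx": 6.0, "HDO": 30.0, "Glc": 8.0},
    "healthy": {"Lac": 0.5, "Glx": 9.2, "HDO": 30.0, "Glc": 8.0},
}


@dataclass(frozen=True)
class ProtocolParams:
    """Acquisition parameters of a (simulated) CSI protocol."""

    tr_s: float
    pulse_duration_s: float
    voltages_v: tuple
    spectral_bw_hz: float
    n_samples: int
    pulse_shape_integral: float = 1.0          # 1.0 for a rectangular pulse
    gamma_hz_per_t: float = constants.GAMMA_2H_HZ_PER_T

    def __post_init__(self):
        object.__setattr__(self, "voltages_v", tuple(float(v) for v in self.voltages_v))
        for name in ("tr_s", "pulse_duration_s", "spectral_bw_hz",
                     "pulse_shape_integral", "gamma_hz_per_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")
        v = np.asarray(self.voltages_v)
        if v.size == 0 or np.any(v <= 0):
            raise ValueError("voltages_v must be non-empty and positive")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("voltages_v must be strictly increasing")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.spectral_bw_hz

    @property
    def flip_per_volt_rad(self) -> float:
        """β = 2π·γ(²H)·T_P·∫f in rad per (V · μT/V)."""
        return (2.0 * np.pi * self.gamma_hz_per_t * 1e-6
                * self.pulse_duration_s * self.pulse_shape_integral)

    @classmethod
    def voltage_series(cls, n_samples: int = 1024) -> "ProtocolParams":
        """Transmit-calibration series: nine 4 ms rectangular pulses,
        25–225 V in 25 V steps, TR 1 s, 5 kHz bandwidth."""
        return cls(tr_s=1.0, pulse_duration_s=4e-3,
                   voltages_v=tuple(np.arange(25.0, 226.0, 25.0)),
                   spectral_bw_hz=5000.0, n_samples=n_samples)

    @classmethod
    def main_scan(cls, n_samples: int = 1024) -> "ProtocolParams":
        """Main/reference scan: 1 ms rectangular pulse at 210 V, TR 250 ms,
        5 kHz bandwidth."""
        return cls(tr_s=0.25, pulse_duration_s=1e-3, voltages_v=(210.0,),
                   spectral_bw_hz=5000.0, n_samples=n_samples)


@dataclass
class MetabolitePeak:
    """Lorentzian resonance template: s(t) = a·e^{iφ}·e^{(−d + i2πf)t}."""

    name: str
    frequency_hz: float
    damping_s_inv: float
    phase_rad: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.damping_s_inv <= 0:
            raise ValueError("damping_s_inv must be positive")


def default_peaks(metabolites: Sequence[str] = ("HDO", "Glc", "Glx", "Lac"),
                  carrier_ppm: float = 4.7) -> List[MetabolitePeak]:
    """Peak templates at the standard DMI chemical shifts with linewidths
    (d/π) of 13–19 Hz, within the range seen in vivo at 7 T."""
    shifts = dict(constants.CHEMICAL_SHIFT_PPM, Fum=FUM_SHIFT_PPM)
    damping = {"HDO": 40.0, "Glc": 60.0, "Glx": 55.0, "Lac": 50.0, "Fum": 45.0}
    peaks = []
    for m in metabolites:
        if m not in shifts:
            raise KeyError(f"no default chemical shift for metabolite {m!r}")
        f = (shifts[m] - carrier_ppm) * constants.HZ_PER_PPM_7T
        peaks.append(MetabolitePeak(m, f, damping.get(m, 50.0)))
    return peaks


@dataclass
class GroundTruth:
    """Known fields underlying a simulated phantom or head."""

    grid: GridGeometry
    b1_plus: np.ndarray                      # (nx,ny,nz), μT/V, ≥ 0
    k_scale: np.ndarray                      # (nx,ny,nz), signal gain
    b1_minus: np.ndarray                     # (nx,ny,nz,nchan), complex
    noise_cov: np.ndarray                    # (nchan,nchan), Hermitian PD
    concentrations: Dict[str, np.ndarray]    # metabolite -> (nx,ny,nz) mol/L
    t1_map: Dict[str, float]                 # metabolite -> seconds
    region_labels: np.ndarray                # (nx,ny,nz) int codes
    seed: int = 0
    scenario: str = ""

    def __post_init__(self):
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.b1_minus.shape[3]

    def mask(self) -> np.ndarray:
        return self.region_labels > 0

    def validate(self) -> None:
        shape = tuple(self.grid.matrix)
        if self.b1_plus.shape != shape or np.any(self.b1_plus < 0):
            raise ValueError("b1_plus must be a non-negative field on the grid")
        if self.b1_minus.shape[:3] != shape:
            raise ValueError("b1_minus spatial shape mismatch")
        xi = np.asarray(self.noise_cov)
        if xi.shape != (self.n_channels, self.n_channels):
            raise ValueError("noise_cov shape must match channel count")
        if not np.allclose(xi, xi.conj().T, atol=1e-12):
            raise ValueError("noise_cov must be Hermitian")
        if np.any(np.linalg.eigvalsh(xi) <= 0):
            raise ValueError("noise_cov must be positive definite")
        for m, c in self.concentrations.items():
            if c.shape != shape or np.any(c < 0):
                raise ValueError(f"concentration field {m!r} invalid")
        for m, t1 in self.t1_map.items():
            if t1 <= 0:
                raise ValueError(f"T1 for {m!r} must be positive")


def flip_angle_rad(b1_plus_ut_per_v, voltage_v: float,
                   protocol: ProtocolParams) -> np.ndarray:
    """Flip angle θ = β·V·B1+ with β = 2π·γ·T_P·∫f."""
    return protocol.flip_per_volt_rad * voltage_v * np.asarray(b1_plus_ut_per_v)


def saturation_amplitude(theta_rad, tr_s: float, t1_s: float) -> np.ndarray:
    """Steady-state spoiled-sequence signal factor
    sin θ · (1 − E) / (1 − cos θ · E), E = e^{−TR/T1}."""
    e = np.exp(-tr_s / t1_s)
    theta = np.asarray(theta_rad, dtype=float)
    return np.sin(theta) * (1.0 - e) / (1.0 - np.cos(theta) * e)


# ---------------------------------------------------------------------------
# scenario builders


def _smooth_field(grid: GridGeometry, rng: np.random.Generator,
                  base: float, variation: float, n_blobs: int = 3) -> np.ndarray:
    """Smooth positive field: base level plus a gentle linear gradient and a
    few broad Gaussian blobs (positions/signs drawn from ``rng``)."""
    x, y, z = grid.center_coordinates_mm()
    fov = np.asarray(grid.fov_mm)
    f = np.ones_like(x)
    grad = rng.uniform(-1.0, 1.0, size=3)
    f += 0.3 * variation * (grad[0] * x / fov[0] + grad[1] * y / fov[1]
                            + grad[2] * z / fov[2])
    for _ in range(n_blobs):
        c = rng.uniform(-0.3, 0.3, size=3) * fov
        w = rng.uniform(0.3, 0.6) * fov.mean()
        s = rng.choice([-1.0, 1.0])
        r2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        f += s * variation * np.exp(-r2 / (2.0 * w ** 2))
    return base * np.clip(f, 0.2, None)


def _channel_sensitivities(grid: GridGeometry, n_channels: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Complex receive fields for loop elements arranged around the head:
    magnitude falls off with distance from the element, phase varies
    linearly across the FOV with a per-channel offset."""
    x, y, z = grid.center_coordinates_mm()
    fov = np.asarray(grid.fov_mm)
    radius = 0.55 * float(np.hypot(fov[0], fov[1])) / 2.0 * 2.0  # just outside FOV
    b = np.empty(tuple(grid.matrix) + (n_channels,), dtype=np.complex128)
    for k in range(n_channels):
        ang = 2.0 * np.pi * k / n_channels + rng.uniform(-0.1, 0.1)
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        cz = rng.uniform(-0.2, 0.2) * fov[2]
        d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        mag = radius / (d + 0.3 * radius)
        phase = (rng.uniform(0, 2 * np.pi)
                 + 2.0 * np.pi * (x * np.cos(ang) + y * np.sin(ang)) / (4.0 * fov[0]))
        b[..., k] = mag * np.exp(1j * phase)
    return b


def _noise_covariance(n_channels: int, rng: np.random.Generator,
                      sigma: float = 1.0, coupling: float = 0.25) -> np.ndarray:
    """Hermitian PD channel covariance with moderate off-diagonal coupling."""
    a = np.eye(n_channels) + coupling * (
        rng.standard_normal((n_channels, n_channels))
        + 1j * rng.standard_normal((n_channels, n_channels))) / np.sqrt(2 * n_channels)
    xi = a @ a.conj().T
    # normalize mean channel variance to sigma^2
    xi *= sigma ** 2 / np.real(np.trace(xi) / n_channels)
    return xi


def _ellipsoid_mask(grid: GridGeometry, semi_axes_mm, center_mm=(0, 0, 0)) -> np.ndarray:
    x, y, z = grid.center_coordinates_mm()
    a, b, c = semi_axes_mm
    return ((x - center_mm[0]) ** 2 / a ** 2 + (y - center_mm[1]) ** 2 / b ** 2
            + (z - center_mm[2]) ** 2 / c ** 2) <= 1.0


def make_phantom_truth(scenario: str,
                       grid: Optional[GridGeometry] = None,
                       n_channels: int = 4,
                       seed: int = 0,
                       noise_sigma: float = 1.0,
                       t1_hdo_s: float = constants.REFERENCE_PHANTOM_T1_S,
                       ) -> GroundTruth:
    """Build ground-truth fields for one of three scenarios.

    ``uniform_reference``: head-shaped (ellipsoidal) shell of 1.14 mol/L HDO —
    the calibration phantom. ``multi_compartment``: 0.2 mol/L HDO bath with
    two 40 mm spheres carrying Lac (0.78 mol/L) and Fum (0.5 mol/L) deuteron
    pools. ``brain_with_tumor``: ellipsoidal brain at natural-abundance
    baseline with a spherical tumor sub-region (distinct kinetics are applied
    by :func:`simulate_longitudinal_study`).
    """
    if grid is None:
        grid = GridGeometry((16, 16, 8), (220.0, 200.0, 320.0))
    if any(n < 4 for n in grid.matrix):
        raise ValueError("grid must be at least 4 voxels per axis")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)

    # mean transmit efficiency ~0.82 μT/√W ≈ 0.116 μT/V (50 Ω), ±25% structure
    b1_plus = _smooth_field(grid, rng, base=0.116, variation=0.25)
    k_scale = _smooth_field(grid, rng, base=1.0, variation=0.1)
    b1_minus = _channel_sensitivities(grid, n_channels, rng)
    xi = _noise_covariance(n_channels, rng, sigma=noise_sigma)

    shape = tuple(grid.matrix)
    labels = np.zeros(shape, dtype=np.int16)
    conc: Dict[str, np.ndarray] = {}
    fov = np.asarray(grid.fov_mm)
    head = _ellipsoid_mask(grid, 0.42 * fov)

    if scenario == "uniform_reference":
        labels[head] = LABELS["bath"]
        c = np.zeros(shape)
        c[head] = constants.REFERENCE_PHANTOM_CONC_MOL_L
        conc["HDO"] = c
        t1 = {"HDO": t1_hdo_s}
    elif scenario == "multi_compartment":
        labels[head] = LABELS["bath"]
        ball_r = 20.0  # mm, table-tennis ball
        lac_ball = _ellipsoid_mask(grid, (ball_r,) * 3, (-0.18 * fov[0], 0, 0))
        fum_ball = _ellipsoid_mask(grid, (ball_r,) * 3, (+0.18 * fov[0], 0, 0))
        labels[lac_ball] = LABELS["lac_ball"]
        labels[fum_ball] = LABELS["fum_ball"]
        hdo = np.zeros(shape)
        hdo[labels == LABELS["bath"]] = 0.2
        lac = np.zeros(shape)
        lac[lac_ball] = 0.78
        fum = np.zeros(shape)
        fum[fum_ball] = 0.5
        conc.update(HDO=hdo, Lac=lac, Fum=fum)
        t1 = {"HDO": 0.567, "Lac": 0.251, "Fum": 0.314}
    elif scenario == "brain_with_tumor":
        brain = _ellipsoid_mask(grid, 0.38 * fov)
        labels[brain] = LABELS["brain"]
        tumor = _ellipsoid_mask(grid, (25.0,) * 3,
                                (0.15 * fov[0], 0.12 * fov[1], 0.0))
        tumor &= brain
        labels[tumor] = LABELS["tumor"]
        base = {"HDO": 9.0e-3, "Glc": 0.1e-3, "Glx": 0.1e-3, "Lac": 0.1e-3}
        for m, v in base.items():
            c = np.zeros(shape)
            c[brain] = v
            conc[m] = c
        t1 = dict(constants.T1_LITERATURE_S)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    return GroundTruth(grid=grid, b1_plus=b1_plus, k_scale=k_scale,
                       b1_minus=b1_minus, noise_cov=xi, concentrations=conc,
                       t1_map=t1, region_labels=labels, seed=seed,
                       scenario=scenario)


# ---------------------------------------------------------------------------
# signal simulation


def _peaks_for_truth(truth: GroundTruth) -> List[MetabolitePeak]:
    return default_peaks(tuple(truth.concentrations.keys()))


def simulate_csi_scan(truth: GroundTruth,
                      protocol: ProtocolParams,
                      voltage_v: float,
                      peaks: Optional[Sequence[MetabolitePeak]] = None,
                      add_noise: bool = True,
                      seed: int = 0,
                      concentrations: Optional[Dict[str, np.ndarray]] = None,
                      ) -> SpectralStack:
    """Simulate one CSI acquisition at a single excitation voltage.

    Per voxel r and channel k the FID is
        FID_k(t) = B1−_k(r) · Σ_m A_m(r) · e^{iφ_m} · e^{(−d_m + i2πf_m)t},
    with A_m(r) = k_scale(r)·[m](r)·sinθ(1−E_m)/(1−cosθ·E_m), the
    steady-state amplitude at flip θ(r) = β·V·B1+(r). Channel noise is drawn
    i.i.d. over time from CN(0, Ξ) when ``add_noise`` is set.
    """
    conc = concentrations if concentrations is not None else truth.concentrations
    if peaks is None:
        peaks = default_peaks(tuple(conc.keys()))
    peak_by_name = {p.name: p for p in peaks}
    missing = set(conc) - set(peak_by_name)
    if missing:
        raise ValueError(f"no peak template for metabolites {sorted(missing)}")

    nx, ny, nz = truth.grid.matrix
    nc, npts = truth.n_channels, protocol.n_samples
    t = np.arange(npts) * protocol.dwell_s
    theta = flip_angle_rad(truth.b1_plus, voltage_v, protocol)

    # voxel signal summed over metabolites: (nx,ny,nz,npts)
    signal = np.zeros((nx, ny, nz, npts), dtype=np.complex128)
    for m, c in conc.items():
        p = peak_by_name[m]
        amp = truth.k_scale * c * saturation_amplitude(theta, protocol.tr_s,
                                                       truth.t1_map[m])
        basis = p.amplitude * np.exp(1j * p.phase_rad) * np.exp(
            (-p.damping_s_inv + 2j * np.pi * p.frequency_hz) * t)
        signal += amp[..., None] * basis[None, None, None, :]

    fids = truth.b1_minus[..., :, None] * signal[..., None, :]

    if add_noise:
        rng = np.random.default_rng(seed)
        fids = fids + draw_channel_noise(truth.noise_cov, (nx, ny, nz, npts), rng)

    return SpectralStack(fids=fids, grid=truth.grid, dwell_s=protocol.dwell_s,
                         voltage_v=float(voltage_v),
                         meta={"seed": seed, "add_noise": add_noise})


def draw_channel_noise(noise_cov: np.ndarray, shape, rng) -> np.ndarray:
    """Complex Gaussian noise with E[n n†] = Ξ across the channel axis.

    Returns an array of shape ``shape[:-1] + (nchan, shape[-1])`` matching the
    (..., channel, time) layout of :class:`SpectralStack` FIDs.
    """
    nc = noise_cov.shape[0]
    chol = np.linalg.cholesky(noise_cov)
    w = (rng.standard_normal(shape[:-1] + (nc, shape[-1]))
         + 1j * rng.standard_normal(shape[:-1] + (nc, shape[-1]))) * np.sqrt(0.5)
    return np.einsum("ij,...jt->...it", chol, w)


def simulate_voltage_series(truth: GroundTruth, protocol: ProtocolParams,
                            add_noise: bool = True, seed: int = 0,
                            ) -> List[SpectralStack]:
    """One scan per protocol voltage with independent noise draws."""
    children = np.random.SeedSequence(seed).spawn(len(protocol.voltages_v))
    return [simulate_csi_scan(truth, protocol, v, add_noise=add_noise,
                              seed=int(cs.generate_state(1)[0] % (2 ** 31)))
            for v, cs in zip(protocol.voltages_v, children)]


def simulate_longitudinal_study(truth: GroundTruth, protocol: ProtocolParams,
                                timepoints_min: Sequence[float],
                                rates: Optional[Dict[str, Dict[str, float]]] = None,
                                region_names: Optional[Dict[int, str]] = None,
                                add_noise: bool = True, seed: int = 0,
                                ) -> List[SpectralStack]:
    """Time series of scans with region-wise linear concentration evolution.

    ``rates`` maps region name -> metabolite -> μmol/L/min; defaults to
    :data:`DEFAULT_RATES` with brain = "nawm", tumor = "tumor". Negative
    resulting concentrations are clipped at zero (and logged).
    """
    tp = np.asarray(timepoints_min, dtype=float)
    if tp.size == 0 or (tp.size > 1 and np.any(np.diff(tp) <= 0)):
        raise ValueError("timepoints_min must be non-empty, strictly increasing")
    if rates is None:
        rates = DEFAULT_RATES
    if region_names is None:
        region_names = {LABELS["brain"]: "nawm", LABELS["tumor"]: "tumor"}

    voltage = protocol.voltages_v[0]
    children = np.random.SeedSequence(seed).spawn(tp.size)
    stacks = []
    for t_min, cs in zip(tp, children):
        conc_t = {}
        for m, c0 in truth.concentrations.items():
            c = c0.copy()
            for label, rname in region_names.items():
                rate = rates.get(rname, {}).get(m, 0.0) * 1e-6  # mol/L/min
                c[truth.region_labels == label] += rate * t_min
            if np.any(c < 0):
                log.warning("clipping negative [%s] at t=%g min", m, t_min)
                c = np.clip(c, 0.0, None)
            conc_t[m] = c
        stack = simulate_csi_scan(
            truth, protocol, voltage, add_noise=add_noise,
            seed=int(cs.generate_state(1)[0] % (2 ** 31)),
            concentrations=conc_t)
        stack.time_min = float(t_min)
        stacks.append(stack)
    return stacks


def simulate_prescan(noise_cov: np.ndarray, n_samples: int, n_channels: int,
                     seed: int = 0) -> SpectralStack:
    """No-RF prescan: zero-mean correlated channel noise, no signal."""
    xi = np.asarray(noise_cov)
    if xi.shape != (n_channels, n_channels):
        raise ValueError("noise_cov shape must be (n_channels, n_channels)")
    if not np.allclose(xi, xi.conj().T, atol=1e-12):
        raise ValueError("noise_cov must be Hermitian")
    if np.any(np.linalg.eigvalsh(xi) <= 0):
        raise ValueError("noise_cov must be positive definite")
    rng = np.random.default_rng(seed)
    if n_samples == 0:
        fids = np.zeros((1, 1, 1, n_channels, 0), dtype=np.complex128)
    else:
        fids = draw_channel_noise(xi, (1, 1, 1, n_samples), rng)
    grid = GridGeometry((1, 1, 1), (1.0, 1.0, 1.0))
    return SpectralStack(fids=fids, grid=grid, dwell_s=1.0,
                         meta={"prescan": True, "seed": seed})


def noise_sigma_for_amplitude_snr(truth: GroundTruth, protocol: ProtocolParams,
                                  voltage_v: float, snr: float,
                                  metabolite: str = "HDO") -> float:
    """Per-sample complex noise SD giving a target SNR on the extracted
    combined amplitude of ``metabolite`` at the median masked voxel.

    The least-squares amplitude estimate from a known template m(t) has
    SD σ/‖m‖; here ‖m‖² = A²·Σ_t e^{−2dt} for a unit-phase Lorentzian with
    combined amplitude A = ‖B1−‖·k_scale·[m]·saturation.
    """
    peak = {p.name: p for p in _peaks_for_truth(truth)}[metabolite]
    t = np.arange(protocol.n_samples) * protocol.dwell_s
    template_norm = np.sqrt(np.sum(np.exp(-2.0 * peak.damping_s_inv * t)))
    theta = flip_angle_rad(truth.b1_plus, voltage_v, protocol)
    sat = saturation_amplitude(theta, protocol.tr_s, truth.t1_map[metabolite])
    amp = (np.linalg.norm(truth.b1_minus, axis=-1) * truth.k_scale
           * truth.concentrations[metabolite] * np.abs(sat))
    a = float(np.median(amp[truth.mask() & (truth.concentrations[metabolite] > 0)]))
    return a * template_norm / snr


def with_noise_cov(truth: GroundTruth, noise_cov: np.ndarray) -> GroundTruth:
    """Copy of ``truth`` with a replacement channel noise covariance."""
    return replace(truth, noise_cov=np.asarray(noise_cov, dtype=np.complex128))


def scale_noise(truth: GroundTruth, sigma: float) -> GroundTruth:
    """Copy of ``truth`` with Ξ rescaled so the mean channel SD is ``sigma``."""
    xi = truth.noise_cov
    cur = np.sqrt(np.real(np.trace(xi)) / xi.shape[0])
    return with_noise_cov(truth, xi * (sigma / cur) ** 2)
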