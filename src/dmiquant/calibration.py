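"""Transmit/receive calibration from a reference-phantom voltage series.

The chain: estimate the channel noise covariance Ξ from a no-RF prescan;
stack all voltage-series spectra per voxel into a joint channels × (voltages
· points) matrix and combine them with a whitened rank-1 SVD; fit a model
spectrum to the strongest combined spectrum; project it onto every
per-channel/per-voltage spectrum to get complex amplitudes; fit the
steady-state variable-flip-angle curve for B1+(r) and k(r); solve linearly
for the complex receive sensitivities B1−_k(r); and form uniform-sensitivity
(Roemer) weights w = Ξ⁻¹B1− / √(B1−†Ξ⁻¹B1−).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.linalg import solve_triangular
from scipy.optimize import least_squares

from .containers import SpectralStack
from .fitting import (PeakTemplate, PriorKnowledge, fit_fid,
                      model_spectrum)
from .grids import GridGeometry
from .synthetic import ProtocolParams, saturation_amplitude

log = logging.getLogger(__name__)

#: Normalized residual above which a transmit-fit voxel is marked invalid.
RESIDUAL_THRESHOLD = 0.2


@dataclass
class NoiseCovariance:
    """Hermitian channel noise covariance Ξ with its sample count."""

    xi: np.ndarray
    n_samples_used: int

    def __post_init__(self):
        xi = np.asarray(self.xi, dtype=np.complex128)
        if xi.ndim != 2 or xi.shape[0] != xi.shape[1]:
            raise ValueError("xi must be square")
        if not np.allclose(xi, xi.conj().T, atol=1e-12 * max(1.0, np.abs(xi).max())):
            raise ValueError("xi must be Hermitian")
        self.xi = 0.5 * (xi + xi.conj().T)
        if np.any(np.linalg.eigvalsh(self.xi) <= 0):
            raise ValueError("xi must be positive definite")

    @property
    def n_channels(self) -> int:
        return self.xi.shape[0]

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor L with Ξ = L L†."""
        return np.linalg.cholesky(self.xi)

    def whiten(self, x: np.ndarray) -> np.ndarray:
        """Apply L⁻¹ along the first axis of a (channels, ...) array."""
        return solve_triangular(self.cholesky(), x, lower=True)

    def inverse_apply(self, b: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.xi, b)


@dataclass
class CoilWeights:
    """Per-voxel complex channel weights; combined = Σ_k conj(w_k)·S_k."""

    w: np.ndarray                 # (nx,ny,nz,nchan)
    valid: np.ndarray             # (nx,ny,nz) bool
    grid: GridGeometry


@dataclass
class AmplitudeTable:
    """Complex amplitudes relative to the model spectrum.

    ``a_kj``: per (channel, voltage), shape (nx,ny,nz,nchan,nvolt);
    ``a_j``: combined per voltage, shape (nx,ny,nz,nvolt).
    """

    a_kj: np.ndarray
    a_j: np.ndarray
    voltages_v: np.ndarray
    valid: np.ndarray


@dataclass
class TransmitMap:
    """Voxel-wise transmit efficiency B1+ (μT/V) and overall scale k."""

    b1_plus: np.ndarray
    k_scale: np.ndarray
    fit_residual: np.ndarray
    valid_mask: np.ndarray
    grid: GridGeometry


@dataclass
class ReceiveMap:
    """Complex per-channel receive sensitivities (with k(r) distributed
    across channels) and the max-signal voltage index used as the per-voxel
    phase reference."""

    b1_minus: np.ndarray          # (nx,ny,nz,nchan)
    phase_reference: np.ndarray   # (nx,ny,nz) int
    valid_mask: np.ndarray
    grid: GridGeometry


@dataclass
class CalibrationBundle:
    """Everything needed to quantify a matched main scan."""

    xi: NoiseCovariance
    transmit: TransmitMap
    receive: ReceiveMap
    weights: CoilWeights
    reference_fit_amplitude: Optional[np.ndarray] = None  # Ŝ_P(r)
    reference_flip_rad: Optional[np.ndarray] = None


def estimate_noise_covariance(prescan) -> NoiseCovariance:
    """Sample covariance (1/N)·Σ n n† from noise-only data.

    ``prescan`` is a noise-only :class:`SpectralStack` or a complex array
    whose leading axis is channels. Requires at least 10 samples per channel
    and a full-rank result.
    """
    if isinstance(prescan, SpectralStack):
        x = prescan.fids.reshape(-1, prescan.n_channels, prescan.n_points)
        x = np.moveaxis(x, 1, 0).reshape(prescan.n_channels, -1)
    else:
        x = np.asarray(prescan, dtype=np.complex128)
        x = x.reshape(x.shape[0], -1)
    nc, n = x.shape
    if n < 10 * nc:
        raise ValueError(f"too few noise samples: {n} for {nc} channels "
                         f"(need >= {10 * nc})")
    xi = (x @ x.conj().T) / n
    xi = 0.5 * (xi + xi.conj().T)
    ev = np.linalg.eigvalsh(xi)
    if ev.min() <= 1e-12 * max(ev.max(), 1e-300):
        diag = np.real(np.diag(xi))
        raise ValueError(
            "rank-deficient noise covariance; per-channel variances: "
            + np.array2string(diag, precision=3))
    return NoiseCovariance(xi=xi, n_samples_used=n)


def _stack_joint_spectra(stacks: Sequence[SpectralStack]) -> np.ndarray:
    """Joint per-voxel spectra: (nx,ny,nz,nchan,nvolt,npts)."""
    spectra = [s.spectra() for s in stacks]
    return np.stack(spectra, axis=-2)


def joint_wsvd(stacks: Sequence[SpectralStack], xi: NoiseCovariance
               ) -> Tuple[CoilWeights, np.ndarray]:
    """Whitened rank-1 combination of all voltage-series spectra per voxel.

    Per voxel, the channels × (voltages·points) joint matrix X is whitened
    with L⁻¹ (Ξ = L L†); the leading left singular vector u gives weights
    w = L⁻†u, so combined = w†X is the maximum-likelihood rank-1 combination.
    The global phase is fixed so the largest-magnitude sample of the
    max-signal voltage's combined spectrum is real and positive.

    Returns the data-driven weights and combined spectra with shape
    (nx,ny,nz,nvolt,npts).
    """
    if not stacks:
        raise ValueError("need at least one stack")
    nc = stacks[0].n_channels
    if nc != xi.n_channels:
        raise ValueError("channel count mismatch between stacks and xi")
    grid = stacks[0].grid
    for s in stacks:
        if s.grid != grid or s.n_channels != nc:
            raise ValueError("all stacks must share grid and channel count")

    joint = _stack_joint_spectra(stacks)           # (nx,ny,nz,nc,nv,np)
    nx, ny, nz, _, nv, npts = joint.shape
    flat = joint.reshape(-1, nc, nv * npts)
    n_vox = flat.shape[0]

    chol = xi.cholesky()
    w_all = np.zeros((n_vox, nc), dtype=np.complex128)
    combined = np.zeros((n_vox, nv * npts), dtype=np.complex128)
    valid = np.zeros(n_vox, dtype=bool)

    for v in range(n_vox):
        x = flat[v]
        if not np.any(x):
            continue
        xw = solve_triangular(chol, x, lower=True)
        gram = xw @ xw.conj().T                    # (nc,nc) Hermitian
        evals, evecs = np.linalg.eigh(gram)
        u = evecs[:, -1]
        w = solve_triangular(chol.conj().T, u, lower=False)
        comb = w.conj() @ x
        # per-voltage energy -> max-signal voltage for the phase convention
        per_volt = comb.reshape(nv, npts)
        jstar = int(np.argmax(np.linalg.norm(per_volt, axis=1)))
        peak_idx = int(np.argmax(np.abs(per_volt[jstar])))
        phase = np.angle(per_volt[jstar, peak_idx])
        rot = np.exp(-1j * phase)
        w_all[v] = w * rot.conj()                  # combined uses conj(w)
        combined[v] = comb * rot
        valid[v] = True

    weights = CoilWeights(w=w_all.reshape(nx, ny, nz, nc),
                          valid=valid.reshape(nx, ny, nz), grid=grid)
    return weights, combined.reshape(nx, ny, nz, nv, npts)


def combine_channels(stack: SpectralStack, weights: CoilWeights) -> np.ndarray:
    """Weighted channel combination of a stack's FIDs: Σ_k conj(w_k)·FID_k.

    Returns (nx,ny,nz,npts) complex; invalid voxels are zero.
    """
    if stack.grid != weights.grid:
        raise ValueError("grid mismatch between stack and weights")
    out = np.einsum("xyzk,xyzkt->xyzt", weights.w.conj(), stack.fids)
    out[~weights.valid] = 0.0
    return out


def default_phantom_prior(frequency_hz: float = 0.0,
                          damping_s_inv: float = 40.0) -> PriorKnowledge:
    """Single-resonance prior for the reference-phantom HDO peak."""
    return PriorKnowledge([PeakTemplate("HDO", frequency_hz, damping_s_inv)])


def fit_model_spectra(combined: np.ndarray, dwell_s: float,
                      prior: PriorKnowledge,
                      mask: Optional[np.ndarray] = None,
                      noise_sd: Optional[float] = None
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Fit the max-signal combined spectrum per voxel; return the model
    spectra S_M (same shape as one combined spectrum) and the max-voltage
    index per voxel.

    ``combined`` has shape (nx,ny,nz,nvolt,npts) in the frequency domain.
    """
    nx, ny, nz, nv, npts = combined.shape
    s_m = np.zeros((nx, ny, nz, npts), dtype=np.complex128)
    jstar = np.zeros((nx, ny, nz), dtype=int)
    if mask is None:
        mask = np.ones((nx, ny, nz), dtype=bool)
    for ix, iy, iz in np.argwhere(mask):
        per_volt = combined[ix, iy, iz]
        j = int(np.argmax(np.linalg.norm(per_volt, axis=1)))
        jstar[ix, iy, iz] = j
        fid = np.fft.ifft(np.fft.ifftshift(per_volt[j]))
        try:
            fit = fit_fid(fid, dwell_s, prior, noise_sd=noise_sd)
        except ValueError:
            continue
        if fit.converged:
            s_m[ix, iy, iz] = model_spectrum(fit)
    return s_m, jstar


def extract_amplitudes(stacks: Sequence[SpectralStack], combined: np.ndarray,
                       model_spectra: np.ndarray) -> AmplitudeTable:
    """Least-squares complex amplitudes of each spectrum relative to S_M:
    A = ⟨S_M, S⟩ / ⟨S_M, S_M⟩ per (channel, voltage) and per voltage."""
    joint = _stack_joint_spectra(stacks)           # (nx,ny,nz,nc,nv,np)
    denom = np.sum(np.abs(model_spectra) ** 2, axis=-1)   # (nx,ny,nz)
    valid = denom > 0
    safe = np.where(valid, denom, 1.0)
    a_kj = np.einsum("xyzt,xyzkvt->xyzkv", model_spectra.conj(), joint) / safe[..., None, None]
    a_j = np.einsum("xyzt,xyzvt->xyzv", model_spectra.conj(), combined) / safe[..., None]
    a_kj[~valid] = 0.0
    a_j[~valid] = 0.0
    voltages = np.array([s.voltage_v for s in stacks], dtype=float)
    return AmplitudeTable(a_kj=a_kj, a_j=a_j, voltages_v=voltages, valid=valid)


def vfa_amplitude(b1_plus, k, voltages_v, protocol: ProtocolParams,
                  t1_s: float) -> np.ndarray:
    """Steady-state amplitude curve k·sin(βVB1+)(1−E)/(1−cos(βVB1+)E)."""
    theta = protocol.flip_per_volt_rad * np.multiply.outer(
        np.asarray(b1_plus, float), np.asarray(voltages_v, float))
    return np.asarray(k, float)[..., None] * saturation_amplitude(
        theta, protocol.tr_s, t1_s)


def fit_b1_transmit(table: AmplitudeTable, protocol: ProtocolParams,
                    t1_phantom_s: float, grid: GridGeometry,
                    mask: Optional[np.ndarray] = None) -> TransmitMap:
    """Voxel-wise nonlinear fit of (B1+, k) to the magnitude amplitude-vs-
    voltage curve of the variable-flip-angle series."""
    voltages = table.voltages_v
    if voltages.size < 3:
        raise ValueError("need at least 3 voltages to fit (B1+, k)")
    if t1_phantom_s <= 0:
        raise ValueError("t1_phantom_s must be positive")
    beta = protocol.flip_per_volt_rad
    vmax = voltages.max()

    # Flip angles beyond 180° occur at the high-voltage end in practice, so
    # the magnitude curve is fitted; a coarse scan over candidate peak flips
    # (with the linear k solved in closed form) picks the starting point.
    theta_grid = np.linspace(np.deg2rad(5.0), np.deg2rad(300.0), 80)
    b1_grid = theta_grid / (beta * vmax)
    m_grid = np.abs(vfa_amplitude(b1_grid, np.ones_like(b1_grid), voltages,
                                  protocol, t1_phantom_s))   # (ncand, nvolt)

    shape = table.a_j.shape[:3]
    b1 = np.zeros(shape)
    k = np.zeros(shape)
    resid = np.full(shape, np.inf)
    ok = np.zeros(shape, dtype=bool)
    if mask is None:
        mask = table.valid

    for ix, iy, iz in np.argwhere(mask):
        y = np.abs(table.a_j[ix, iy, iz])
        if y.max() <= 0:
            continue
        k_cand = (m_grid @ y) / np.maximum(np.sum(m_grid ** 2, axis=1), 1e-300)
        sse = np.sum((k_cand[:, None] * m_grid - y) ** 2, axis=1)
        best = int(np.argmin(sse))
        b1_0, k_0 = b1_grid[best], max(k_cand[best], 1e-12)

        def residuals(p, y=y):
            return np.abs(vfa_amplitude(p[0], p[1], voltages, protocol,
                                        t1_phantom_s)) - y

        sol = least_squares(residuals, np.array([b1_0, k_0]),
                            bounds=([0.0, 0.0],
                                    [2.0 * b1_grid[-1], np.inf]),
                            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        rnorm = np.linalg.norm(sol.fun) / np.linalg.norm(y)
        b1[ix, iy, iz] = sol.x[0]
        k[ix, iy, iz] = sol.x[1]
        resid[ix, iy, iz] = rnorm
        ok[ix, iy, iz] = bool(sol.success) and rnorm <= RESIDUAL_THRESHOLD

    return TransmitMap(b1_plus=b1, k_scale=k, fit_residual=resid,
                       valid_mask=ok, grid=grid)


def fit_b1_receive(table: AmplitudeTable, transmit: TransmitMap,
                   protocol: ProtocolParams, t1_phantom_s: float
                   ) -> ReceiveMap:
    """Closed-form linear solve for complex per-channel sensitivities.

    With magnetization factors M_j = sin(βV_jB1+)(1−E)/(1−cos(βV_jB1+)E)
    (real, from the fitted B1+), B1−_k = Σ_j M_j·A_{k,j} / Σ_j M_j². The
    Eq. 2 scale k(r) is thereby distributed across the receive channels.
    """
    m_j = vfa_amplitude(transmit.b1_plus, np.ones_like(transmit.b1_plus),
                        table.voltages_v, protocol, t1_phantom_s)  # (x,y,z,nv)
    denom = np.sum(m_j ** 2, axis=-1)
    usable = transmit.valid_mask & (denom > 0)
    safe = np.where(usable, denom, 1.0)
    b1m = np.einsum("xyzv,xyzkv->xyzk", m_j, table.a_kj) / safe[..., None]
    b1m[~usable] = 0.0
    phase_ref = np.argmax(np.abs(table.a_j), axis=-1)
    return ReceiveMap(b1_minus=b1m, phase_reference=phase_ref,
                      valid_mask=usable, grid=transmit.grid)


def roemer_weights(receive: ReceiveMap, xi: NoiseCovariance) -> CoilWeights:
    """Uniform-sensitivity weights w = Ξ⁻¹B1− / √(B1−†Ξ⁻¹B1−) per voxel
    (so that w†Ξw = 1); zero-sensitivity voxels are flagged invalid."""
    b = receive.b1_minus
    xib = np.einsum("ij,xyzj->xyzi", np.linalg.inv(xi.xi), b)
    quad = np.real(np.einsum("xyzi,xyzi->xyz", b.conj(), xib))
    ok = receive.valid_mask & (quad > 0)
    safe = np.where(ok, quad, 1.0)
    w = xib / np.sqrt(safe)[..., None]
    w[~ok] = 0.0
    return CoilWeights(w=w, valid=ok, grid=receive.grid)


def resample_b1_grid(values: np.ndarray, src_grid: GridGeometry,
                     dst_grid: GridGeometry
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Trilinear resampling of a field between CSI grids sharing a FOV.

    Interpolation is in physical coordinates of the voxel centers;
    destination centers outside the source-center hull are filled by
    nearest-edge extrapolation and flagged. Returns (resampled,
    extrapolated_mask). Works on real or complex fields; trailing axes
    beyond the three spatial ones are resampled independently.
    """
    if not src_grid.same_fov(dst_grid):
        raise ValueError("source and destination grids must share FOV and offset")
    values = np.asarray(values)
    if values.shape[:3] != tuple(src_grid.matrix):
        raise ValueError("values shape does not match source grid")
    src_axes = [src_grid.axis_centers_mm(a) for a in range(3)]
    xd, yd, zd = dst_grid.center_coordinates_mm()
    pts = np.stack([xd.ravel(), yd.ravel(), zd.ravel()], axis=-1)

    extrapolated = np.zeros(pts.shape[0], dtype=bool)
    clipped = pts.copy()
    for a in range(3):
        lo, hi = src_axes[a][0], src_axes[a][-1]
        outside = (pts[:, a] < lo) | (pts[:, a] > hi)
        extrapolated |= outside
        clipped[:, a] = np.clip(pts[:, a], lo, hi)

    trailing = values.shape[3:]
    flatv = values.reshape(tuple(src_grid.matrix) + (-1,))
    out = np.empty((pts.shape[0], flatv.shape[-1]), dtype=values.dtype)
    for c in range(flatv.shape[-1]):
        interp = RegularGridInterpolator(src_axes, flatv[..., c],
                                         method="linear", bounds_error=False)
        out[:, c] = interp(clipped)
    out = out.reshape(tuple(dst_grid.matrix) + trailing)
    return out, extrapolated.reshape(dst_grid.matrix)


def calibrate(stacks: Sequence[SpectralStack], prescan,
              protocol: ProtocolParams, t1_phantom_s: float,
              prior: Optional[PriorKnowledge] = None,
              mask: Optional[np.ndarray] = None) -> CalibrationBundle:
    """Run the full calibration chain on a reference-phantom voltage series."""
    xi = (prescan if isinstance(prescan, NoiseCovariance)
          else estimate_noise_covariance(prescan))
    if prior is None:
        prior = default_phantom_prior()
    grid = stacks[0].grid
    dwell = stacks[0].dwell_s
    wsvd_weights, combined = joint_wsvd(stacks, xi)
    if mask is None:
        mask = wsvd_weights.valid
    # signal-based pre-mask: drop voxels whose strongest combined spectrum is
    # indistinguishable from noise
    energy = np.linalg.norm(combined, axis=(-2, -1))
    mask = mask & (energy > 0)
    s_m, _ = fit_model_spectra(combined, dwell, prior, mask=mask)
    table = extract_amplitudes(stacks, combined, s_m)
    transmit = fit_b1_transmit(table, protocol, t1_phantom_s, grid,
                               mask=mask & table.valid)
    receive = fit_b1_receive(table, transmit, protocol, t1_phantom_s)
    weights = roemer_weights(receive, xi)
    log.info("calibration: %d/%d voxels valid", int(weights.valid.sum()),
             weights.valid.size)
    return CalibrationBundle(xi=xi, transmit=transmit, receive=receive,
                             weights=weights)
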