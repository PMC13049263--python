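"""Time-domain fitting of exponentially damped sinusoids with prior
knowledge (AMARES-style) and Cramér–Rao lower bounds.

The model per peak m is s_m(t) = a_m · e^{iφ_m} · e^{(−d_m + i2πf_m) t};
the fit minimizes ‖Σ_m s_m(t_n) − y(t_n)‖² over the free parameters with
per-parameter free / fixed / bounded statuses. Pure Lorentzians with zero
dead time are assumed (no first-order phase), matching an ultrashort-TE
CSI readout.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .synthetic import MetabolitePeak

#: Parameter names per peak, in canonical order.
PARAM_NAMES = ("amplitude", "frequency_hz", "damping_s_inv", "phase_rad")

FREE = ("free",)


def fixed(value: float) -> tuple:
    if not np.isfinite(value):
        raise ValueError("fixed value must be finite")
    return ("fixed", float(value))


def bounded(lo: float, hi: float) -> tuple:
    if not lo < hi:
        raise ValueError("bounded status requires lo < hi")
    return ("bounded", float(lo), float(hi))


@dataclass
class PeakTemplate:
    """One resonance in the prior: starting values plus statuses."""

    name: str
    frequency_hz: float
    damping_s_inv: float
    phase_rad: float = 0.0
    amplitude: float = 1.0
    statuses: Dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        for p in self.statuses:
            if p not in PARAM_NAMES:
                raise KeyError(f"unknown parameter {p!r}")

    def status(self, param: str) -> tuple:
        return self.statuses.get(param, FREE)

    def initial(self, param: str) -> float:
        return float(getattr(self, {"amplitude": "amplitude",
                                    "frequency_hz": "frequency_hz",
                                    "damping_s_inv": "damping_s_inv",
                                    "phase_rad": "phase_rad"}[param]))

    @classmethod
    def from_peak(cls, peak: MetabolitePeak, **statuses) -> "PeakTemplate":
        return cls(peak.name, peak.frequency_hz, peak.damping_s_inv,
                   peak.phase_rad, abs(peak.amplitude) or 1.0, dict(statuses))


@dataclass
class PriorKnowledge:
    """Prior-knowledge constraints for a multi-peak fit."""

    peaks: List[PeakTemplate]
    shared_phase: bool = False
    carrier_hz: float = 0.0

    def __post_init__(self):
        if not self.peaks:
            raise ValueError("prior must contain at least one peak")
        if all(p.status("amplitude")[0] == "fixed" for p in self.peaks):
            raise ValueError("at least one amplitude must be free")

    @classmethod
    def from_peaks(cls, peaks: Sequence[MetabolitePeak], shared_phase: bool = False,
                   **kwargs) -> "PriorKnowledge":
        return cls([PeakTemplate.from_peak(p) for p in peaks],
                   shared_phase=shared_phase, **kwargs)


@dataclass
class FitResult:
    """Fitted Lorentzian parameters with uncertainties.

    ``crlb`` maps (peak name, parameter) -> standard deviation; fixed
    parameters are absent. ``covariance`` is the free-parameter covariance
    from the inverse Fisher information, ordered as ``free_labels``.
    """

    peaks: List[MetabolitePeak]
    converged: bool
    residual_norm: float
    noise_sd: float
    dwell_s: float
    n_points: int
    crlb: Dict[Tuple[str, str], float] = field(default_factory=dict)
    crlb_percent_amplitude: Dict[str, float] = field(default_factory=dict)
    covariance: Optional[np.ndarray] = None
    free_labels: List[Tuple[str, str]] = field(default_factory=list)
    jacobian: Optional[np.ndarray] = None      # real-stacked, at the solution
    shared_phase: bool = False

    def peak(self, name: str) -> MetabolitePeak:
        for p in self.peaks:
            if p.name == name:
                return p
        raise KeyError(name)

    def amplitude(self, name: str) -> float:
        return float(np.abs(self.peak(name).amplitude))

    def amplitude_covariance(self, names: Sequence[str]) -> np.ndarray:
        """Covariance sub-matrix of the amplitude estimates for ``names``.

        A fixed amplitude contributes zero variance.
        """
        n = len(names)
        cov = np.zeros((n, n))
        idx = {}
        for i, name in enumerate(names):
            lab = (name, "amplitude")
            if lab in self.free_labels:
                idx[i] = self.free_labels.index(lab)
        if self.covariance is not None:
            for i, ii in idx.items():
                for j, jj in idx.items():
                    cov[i, j] = self.covariance[ii, jj]
        return cov


def _wrap_frequency(f_hz: float, bw_hz: float) -> float:
    """Alias a frequency into (−BW/2, BW/2]."""
    f = (f_hz + bw_hz / 2.0) % bw_hz - bw_hz / 2.0
    if f == -bw_hz / 2.0:
        f = bw_hz / 2.0
    return f


class _ParamLayout:
    """Free/fixed bookkeeping for the parameter vector."""

    def __init__(self, prior: PriorKnowledge):
        self.prior = prior
        self.labels: List[Tuple[str, str]] = []   # (peak name, param)
        self.lower: List[float] = []
        self.upper: List[float] = []
        self.x0: List[float] = []
        for pk in prior.peaks:
            for param in PARAM_NAMES:
                if param == "phase_rad" and prior.shared_phase:
                    continue
                self._add(pk, param)
        if prior.shared_phase:
            pk0 = prior.peaks[0]
            st = pk0.status("phase_rad")
            if st[0] != "fixed":
                self.labels.append(("*", "phase_rad"))
                self.x0.append(pk0.initial("phase_rad"))
                self.lower.append(-np.inf)
                self.upper.append(np.inf)

    def _add(self, pk: PeakTemplate, param: str):
        st = pk.status(param)
        if st[0] == "fixed":
            return
        lo, hi = -np.inf, np.inf
        if param == "amplitude":
            lo = 0.0
        elif param == "damping_s_inv":
            lo = 1e-6
        if st[0] == "bounded":
            lo, hi = max(lo, st[1]), min(hi, st[2])
        x0 = min(max(pk.initial(param), lo), hi)
        self.labels.append((pk.name, param))
        self.x0.append(float(x0))
        self.lower.append(lo)
        self.upper.append(hi)

    @property
    def n_free(self) -> int:
        return len(self.labels)

    def unpack(self, x: np.ndarray) -> List[Dict[str, float]]:
        """Full per-peak parameter dicts from the free vector."""
        vals = []
        shared_phase_val = None
        if self.prior.shared_phase:
            if ("*", "phase_rad") in self.labels:
                shared_phase_val = x[self.labels.index(("*", "phase_rad"))]
            else:
                st = self.prior.peaks[0].status("phase_rad")
                shared_phase_val = st[1]
        for pk in self.prior.peaks:
            d = {}
            for param in PARAM_NAMES:
                if param == "phase_rad" and self.prior.shared_phase:
                    d[param] = shared_phase_val
                    continue
                st = pk.status(param)
                if st[0] == "fixed":
                    d[param] = st[1]
                else:
                    d[param] = x[self.labels.index((pk.name, param))]
            vals.append(d)
        return vals


def _model_and_jacobian(x, layout: _ParamLayout, t: np.ndarray):
    """Complex model and complex Jacobian w.r.t. the free parameters."""
    vals = layout.unpack(x)
    n = t.size
    model = np.zeros(n, dtype=np.complex128)
    jac = np.zeros((n, layout.n_free), dtype=np.complex128)
    for pk, v in zip(layout.prior.peaks, vals):
        a, f, d, ph = (v["amplitude"], v["frequency_hz"],
                       v["damping_s_inv"], v["phase_rad"])
        e = np.exp((-d + 2j * np.pi * f) * t + 1j * ph)
        s = a * e
        model += s
        for param, deriv in (("amplitude", e),
                             ("frequency_hz", s * 2j * np.pi * t),
                             ("damping_s_inv", -s * t),
                             ("phase_rad", 1j * s)):
            key = (pk.name, param)
            if param == "phase_rad" and layout.prior.shared_phase:
                key = ("*", "phase_rad")
            if key in layout.labels:
                jac[:, layout.labels.index(key)] += deriv
    return model, jac


def _warm_start_linear(layout: _ParamLayout, fid: np.ndarray, t: np.ndarray):
    """Variable-projection-style start: solve the linear LSQ for complex
    amplitudes at the prior's nonlinear parameters, then seed free
    amplitude/phase entries from the solution."""
    prior = layout.prior
    basis = np.column_stack([
        np.exp((-pk.initial("damping_s_inv")
                + 2j * np.pi * pk.initial("frequency_hz")) * t)
        for pk in prior.peaks])
    coef, *_ = np.linalg.lstsq(basis, fid, rcond=None)
    x0 = np.array(layout.x0, dtype=float)
    for pk, c in zip(prior.peaks, coef):
        ia = (pk.name, "amplitude")
        if ia in layout.labels and abs(c) > 0:
            i = layout.labels.index(ia)
            x0[i] = np.clip(abs(c), layout.lower[i], layout.upper[i])
        ip = (pk.name, "phase_rad")
        if ip in layout.labels and abs(c) > 0:
            x0[layout.labels.index(ip)] = float(np.angle(c))
    if prior.shared_phase and ("*", "phase_rad") in layout.labels:
        weights = np.abs(coef)
        if weights.sum() > 0:
            mean_phase = float(np.angle(np.sum(coef)))
            x0[layout.labels.index(("*", "phase_rad"))] = mean_phase
    return x0


def estimate_noise_sd(fid: np.ndarray, tail_fraction: float = 0.1) -> float:
    """Noise SD per real component from the tail of the FID."""
    n = max(4, int(round(tail_fraction * fid.size)))
    tail = fid[-n:]
    return float(np.std(np.concatenate([tail.real, tail.imag])))


def fit_fid(fid: np.ndarray, dwell_s: float, prior: PriorKnowledge,
            noise_sd: Optional[float] = None) -> FitResult:
    """Fit a complex FID with the prior-knowledge Lorentzian model.

    ``noise_sd`` is the per-real-component noise standard deviation used for
    the CRLBs; when omitted it is estimated from the last 10% of samples.
    Returns a :class:`FitResult`; an all-zero input yields an unconverged
    result with zero amplitudes and flagged CRLBs.
    """
    fid = np.asarray(fid, dtype=np.complex128).ravel()
    if dwell_s <= 0:
        raise ValueError("dwell_s must be positive")
    if not np.all(np.isfinite(fid)):
        raise ValueError("FID contains non-finite samples")
    layout = _ParamLayout(prior)
    if fid.size < 8 * max(layout.n_free, 1):
        raise ValueError(
            f"FID too short: {fid.size} points for {layout.n_free} free parameters")
    t = np.arange(fid.size) * dwell_s
    bw = 1.0 / dwell_s

    if noise_sd is None:
        noise_sd = estimate_noise_sd(fid)

    if not np.any(fid):
        peaks = [MetabolitePeak(pk.name, pk.initial("frequency_hz"),
                                pk.initial("damping_s_inv"),
                                pk.initial("phase_rad"), 0.0)
                 for pk in prior.peaks]
        return FitResult(peaks=peaks, converged=False, residual_norm=0.0,
                         noise_sd=noise_sd, dwell_s=dwell_s, n_points=fid.size,
                         crlb={}, crlb_percent_amplitude={p.name: np.inf
                                                          for p in peaks},
                         free_labels=list(layout.labels),
                         shared_phase=prior.shared_phase)

    x0 = _warm_start_linear(layout, fid, t)

    def residuals(x):
        model, _ = _model_and_jacobian(x, layout, t)
        r = model - fid
        return np.concatenate([r.real, r.imag])

    def jac(x):
        _, j = _model_and_jacobian(x, layout, t)
        return np.vstack([j.real, j.imag])

    sol = least_squares(residuals, x0, jac=jac,
                        bounds=(layout.lower, layout.upper),
                        method="trf", ftol=1e-10, xtol=1e-12, gtol=1e-12,
                        max_nfev=500)

    vals = layout.unpack(sol.x)
    peaks = [MetabolitePeak(pk.name,
                            _wrap_frequency(v["frequency_hz"], bw),
                            v["damping_s_inv"],
                            float(np.angle(np.exp(1j * v["phase_rad"]))),
                            v["amplitude"])
             for pk, v in zip(prior.peaks, vals)]
    _, jc = _model_and_jacobian(sol.x, layout, t)
    jr = np.vstack([jc.real, jc.imag])
    result = FitResult(peaks=peaks, converged=bool(sol.success),
                       residual_norm=float(np.linalg.norm(sol.fun)),
                       noise_sd=noise_sd, dwell_s=dwell_s, n_points=fid.size,
                       free_labels=list(layout.labels), jacobian=jr,
                       shared_phase=prior.shared_phase)
    return compute_crlb(result, noise_sd=noise_sd)


def compute_crlb(fit: FitResult, noise_sd: float,
                 model_jacobian: Optional[np.ndarray] = None) -> FitResult:
    """Populate CRLB fields from the Fisher information at the solution.

    F = (1/σ²)·Re(J†J) over the free parameters (equivalently JᵣᵀJᵣ for the
    real-stacked Jacobian Jᵣ); CRLB = sqrt(diag(F⁻¹)). ``model_jacobian``
    overrides the Jacobian stored on the fit (e.g., a finite-difference
    check). A singular Fisher matrix flags the result with infinite CRLBs.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    jr = model_jacobian if model_jacobian is not None else fit.jacobian
    out = replace(fit, noise_sd=noise_sd)
    out.crlb = {}
    out.crlb_percent_amplitude = {}
    if jr is None or jr.size == 0:
        for p in fit.peaks:
            out.crlb_percent_amplitude[p.name] = np.inf
        out.covariance = None
        return out
    fisher = (jr.T @ jr) / noise_sd ** 2
    try:
        cov = np.linalg.inv(fisher)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
        singular = False
    except np.linalg.LinAlgError:
        cov = np.full_like(fisher, np.inf)
        singular = True
    out.covariance = None if singular else cov
    for i, lab in enumerate(fit.free_labels):
        out.crlb[lab] = np.inf if singular else float(np.sqrt(max(cov[i, i], 0.0)))
    for p in fit.peaks:
        lab = (p.name, "amplitude")
        if lab not in fit.free_labels:
            continue                      # fixed amplitude: no CRLB by convention
        a = abs(p.amplitude)
        sd = out.crlb[lab]
        out.crlb_percent_amplitude[p.name] = (np.inf if (a == 0 or singular)
                                              else 100.0 * sd / a)
    return out


def fix_linewidths(prior: PriorKnowledge, reference_fit: FitResult
                   ) -> PriorKnowledge:
    """Copy of ``prior`` with each peak's damping fixed at the reference
    fit's value (linewidths frozen from the last, highest-SNR timepoint)."""
    if not reference_fit.converged:
        raise ValueError("reference fit did not converge; cannot fix linewidths")
    new = copy.deepcopy(prior)
    for pk in new.peaks:
        d_ref = reference_fit.peak(pk.name).damping_s_inv
        pk.statuses["damping_s_inv"] = fixed(d_ref)
        pk.damping_s_inv = float(d_ref)
    return new


def model_fid(fit: FitResult, n_points: Optional[int] = None,
              dwell_s: Optional[float] = None) -> np.ndarray:
    """Time-domain model evaluated at the fit's parameters."""
    n = n_points if n_points is not None else fit.n_points
    dt = dwell_s if dwell_s is not None else fit.dwell_s
    t = np.arange(n) * dt
    out = np.zeros(n, dtype=np.complex128)
    for p in fit.peaks:
        out += (p.amplitude * np.exp(1j * p.phase_rad)
                * np.exp((-p.damping_s_inv + 2j * np.pi * p.frequency_hz) * t))
    return out


def model_spectrum(fit: FitResult, n_points: Optional[int] = None,
                   dwell_s: Optional[float] = None) -> np.ndarray:
    """Model spectrum S_M: FFT of the fitted time-domain model on the data
    grid (fftshift convention, matching :meth:`SpectralStack.spectra`)."""
    return np.fft.fftshift(np.fft.fft(model_fid(fit, n_points, dwell_s)))
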