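# Methods

This note documents the models, numerical choices and limitations behind
`dmiquant`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Signal model and simulator

The synthetic-data module generates image-domain voxel FIDs for a
multi-channel 3D CSI acquisition:

    FID_k(r, t) = B1⁻_k(r) · Σ_m A_m(r) · e^{iφ_m} · e^{(−d_m + i2πf_m)t},
    A_m(r) = g(r) · [m](r) · sin θ · (1 − E_m) / (1 − cos θ · E_m),

with E_m = e^(−TR/T1_m), flip angle θ(r, V) = 2π·γ(²H)·B1⁺(r)·V·T_P·∫f, and
g(r) a smooth scanner-gain field. The deuterium gyromagnetic ratio is held
at γ = 6.536 MHz/T. Channel noise is complex Gaussian, i.i.d. across time
samples and correlated across channels through a full Hermitian covariance
Ξ (drawn once per phantom; Cholesky-based coloring), matching the model
under which a no-RF prescan estimates Ξ.

Default resonances sit at the standard DMI chemical shifts (HDO 4.7, Glc
3.8, Glx 2.35, Lac 1.3 ppm; fumarate 6.5 ppm for the validation phantom) on
a carrier at the HDO line, 45.7 Hz/ppm at 7 T, with damping constants of
40–60 s⁻¹ (linewidths 13–19 Hz, inside the 11–26 Hz range seen in vivo).
These are configurable; the shifts are field conventions, not measured
here.

Three scenarios mirror the study's phantoms and subjects:

* `uniform_reference` — head-shaped (ellipsoidal) shell of 1.14 mol/L HDO
  deuterons; the calibration phantom.
* `multi_compartment` — 0.2 mol/L HDO bath with two 40 mm spheres holding
  0.78 mol/L Lac and 0.5 mol/L Fum deuteron pools. Note the spheres contain
  no voxel centers on the 16×16×8 acquisition matrix (whose z-voxels are
  40 mm); validation therefore uses the 20×20×16 matrix, the same
  resolution escalation the original validation used.
* `brain_with_tumor` — ellipsoidal brain at a natural-abundance baseline
  (9 mmol/L HDO) with a spherical tumor sub-region. Longitudinal scans
  evolve concentrations linearly per region at defaults of 2.3/1.0/0.5
  μmol/L/min (Lac) and 3.8/6.0/9.2 μmol/L/min (Glx) for
  tumor/normal-appearing/healthy tissue. HDO (30) and Glc (8 μmol/L/min)
  rates are round numbers consistent with post-ingestion trajectories that
  rise by a few mmol/L (HDO) and a fraction of a mmol/L (Glc) over 90 min;
  they carry no analysis weight.

The same seed reproduces bit-identical data, and the coil fields (B1⁺,
B1⁻, Ξ, gain) are drawn before the scenario geometry, so two scenarios
built with one seed share a "coil" — exactly what a matched
reference-phantom calibration assumes.

What the simulator deliberately omits: k-space sampling and acquisition
weighting (so there is no voxel point-spread-function or partial-volume
mixing), B0 inhomogeneity and non-Lorentzian lineshapes, the subcutaneous
lipid "Lac ring", first-order phase. Passing tests therefore demonstrate
the correctness of the estimation chain under its own assumptions, not
robustness to lineshape distortion or bleed between voxels.

## Calibration chain

1. **Ξ** — sample covariance (1/N)ΣnnH of the prescan, Hermitian-symmetrized;
   requires ≥ 10 samples per channel and full rank.
2. **Joint WSVD** — per voxel the spectra of all nine voltage steps are
   stacked into one Nc × (N_V·N_s) matrix, whitened with L⁻¹ (Ξ = LL†,
   Cholesky rather than eigendecomposition — equivalent, cheaper,
   deterministic), and the leading left singular vector u taken from the
   (cheap) Nc×Nc Gram eigenproblem. Weights w = L⁻†u; combined = w†X. The
   per-voxel phase ambiguity is fixed by making the largest-magnitude
   sample of the max-signal voltage's combined spectrum real and positive.
3. **Model spectrum** — the max-signal combined spectrum is fitted with the
   single-resonance prior and the fitted model is projected onto every
   per-channel/per-voltage spectrum, A = ⟨S_M, S⟩/⟨S_M, S_M⟩, giving
   complex amplitude tables.
4. **B1⁺ fit** — per voxel, |A_j| against the magnitude of the steady-state
   curve. Magnitudes (not signed or complex amplitudes) are fitted because
   flips beyond 180° occur at the high-voltage end of the series and
   manifest as sign flips that the magnitude curve represents cleanly;
   phase is common-mode and handled in the receive solve. Initialization
   scans 80 candidate peak flips from 5° to 300° with the linear scale k
   solved in closed form, then refines with bounded least squares
   (tolerances 1e-14). A voxel is invalid when the normalized residual
   exceeds 0.2. On noiseless data the chain recovers B1⁺ to machine
   precision; at amplitude SNR 50 the RMS relative error is ≈0.1% (the
   acceptance test asserts < 2%).
5. **B1⁻ solve** — closed form B1⁻_k = Σ_j M_j A_{k,j} / Σ_j M_j² with the
   real magnetization factors M_j from the fitted B1⁺; the overall scale k
   is thereby distributed across channels, phases preserved.
6. **Weights** — w = Ξ⁻¹B1⁻ / √(B1⁻†Ξ⁻¹B1⁻), i.e. unit output noise. The
   classical uniform-sensitivity normalization divides by the quadratic
   form itself rather than its square root; we keep the square-root form
   deliberately. The choice cancels in the phantom-replacement ratio
   because identical weights multiply the reference and main scans, and the
   tests assert the replacement identity to 1e-6 regardless.

Grid resampling between calibration and main matrices is trilinear in
physical voxel-center coordinates; destination centers outside the source
hull are filled nearest-edge and flagged, and the flag propagates to mask
metadata.

## Spectral fitting and CRLBs

The fitter minimizes ‖Σ_m a_m e^{iφ_m} e^{(−d_m+i2πf_m)t} − y(t)‖² over the
free parameters with per-parameter free/fixed/bounded statuses, a shared
zero-order phase optionally tied across peaks, analytic Jacobians, and a
variable-projection-style warm start (linear solve for complex amplitudes
at the prior's nonlinear parameters). Bounds: amplitudes ≥ 0, dampings > 0.
Optimizer: trust-region reflective, cost tolerance 1e-10, at most 500
evaluations. Frequencies are reported aliased into (−BW/2, BW/2].

CRLBs come from F = (1/σ²)·Re(J†J) over the free parameters only;
CRLB = sqrt(diag(F⁻¹)); fixed parameters carry no bound by convention. σ is
the per-real-component noise SD, estimated from the last 10% of FID samples
when not supplied. A singular Fisher matrix flags the voxel with infinite
CRLB%, which the masks then exclude. Monte-Carlo calibration (500 repeats)
agrees with the reported amplitude CRLB within 15%, and a finite-difference
Fisher matrix reproduces the analytic one to 1e-6.

The ratio-CRLB for R = a_Lac/(a_Lac + a_Glx) is a first-order delta-method
propagation of the amplitude covariance; no published formula exists for
this quantity, and Monte-Carlo draws from the fit covariance agree with the
delta method within 10%.

Linewidth handling for time series: the last (highest-label) timepoint is
fitted with free linewidths, which are then fixed per voxel for all earlier
timepoints. On constant-concentration simulations this does not increase
amplitude variance (asserted).

## Quantification

Amplitudes entering the replacement ratio are magnitudes of the complex
fitted amplitudes (after the global phase convention), which avoids sign
flips at low SNR. The saturation factor uses the per-voxel flip from the
calibrated B1⁺ and the main-scan voltage; metabolite T1s default to the
literature table (Lac 297, Glc 66, Glx 149, HDO 450 ms) and phantom T1s to
their measured values. F is strictly increasing in T1 and decreasing in TR
(property-tested). Masks implement the two-stage quality control above;
mask #2 ⊆ mask #1 structurally.

Two helper calculations are exposed because the interpretation of absolute
HDO maps depends on them: the natural-abundance bound
2 × 55.5 mol/L × (D fraction) × (water fraction), giving 8.9–13.3 mmol/L
for 0.0115–0.015% deuterium and 70–80% brain water; and the deuteron
molarity of a D₂O spike, mass/20.028 × 2/volume. For the 51 g / 4.5 L
reference recipe this yields 1.132 mol/L where the phantom is labelled
1.14 mol/L — a 0.7% discrepancy we report rather than reconcile; the
labelled value is used as [P].

## Kinetics and statistics

Rates are OLS slopes of ROI-mean concentration on time, restricted to
20–90 min after ingestion (the rising, approximately linear phase), in
μmol/L/min. S_Lac is the ratio of the Lac rate to the summed Lac+Glx rates
and is undefined (flagged) when the denominator vanishes.

Paired region comparisons use the Wilcoxon signed-rank test matched by
(patient, timepoint): exact p-values whenever there are no ties or zero
differences, otherwise a Pratt-handled, continuity-corrected normal
approximation; the signed z takes the directional statistic's correction.
All-zero differences return a flagged degenerate result (p = 1) rather than
an error. Exact p-values are verified against brute-force enumeration of
all 2ⁿ sign assignments for n ≤ 12.

Stepwise selection is a greedy bidirectional AIC search from the
intercept-only model over {time, Region, PatientID, age, gender}, ties
breaking toward the smaller model; PatientID enters as dummy-coded
categories. Under a pure-noise response, plain AIC retains a spurious k-df
term with probability P(χ²_k > 2k) (≈16% for one df), so the intercept-only
model is kept ≈73% of the time with two candidates — an inherent property
of AIC, not a defect; the tests calibrate against this derived rate and
against an independent greedy re-implementation.

Mixed models are fitted by maximum likelihood (not REML — LR tests across
models require ML): model 1 adds a Region fixed effect with random
intercepts and slopes by patient (fitted on patient data, where Region is a
within-subject contrast); model 2 has a random intercept; model 3 random
intercept + slope. Time is internally rescaled (÷100) before fitting: the
random-slope variance is ~3 orders of magnitude below the intercept
variance and the unscaled optimization stalls at the boundary; the
reparameterization leaves likelihoods and LR statistics unchanged and
coefficients are reported per minute. Several optimizers are tried and the
best log-likelihood kept (validated against lme4 on shared data).

The LR test refers 2·Δℓ to χ² with df = parameter difference. Testing a
random slope places the variance on the boundary of the parameter space,
so this reference is conservative: the asymptotic null is the mixture
½χ²₁+½χ²₂ (rejection ≈0.032 at nominal 0.05), and the measured
finite-sample type-I error of our implementation is ≈0.02 over 500 null
simulations — conservative, never anti-conservative. A reader requiring
calibrated boundary p-values should halve them or use the mixture
reference.

The statistical validation operates on an ROI-level study generator
(`simulate_roi_study`): per-region linear trajectories with the rate
defaults above, patient random intercepts (SD 0.05 mmol/L) and optional
random slopes, and i.i.d. noise on the ROI means (SD 0.02 mmol/L). The
statistics consume ROI means regardless of origin, so this is the natural
level at which to validate them; the image-domain path from voxels to ROI
means is exercised separately end-to-end at small grid sizes.

## Problem sizes in the shipped tests

The protocol defaults keep the acquisition's own dimensions (1024 points,
5 kHz, nine voltages, 16×16×8 over 220×200×320 mm). The validation suite
runs the same chain at reduced sizes chosen as its standard problem sizes:
8×8×4 grids with 256-point FIDs for exactness checks, the full 16×16×8
matrix for noisy B1⁺ recovery, a central slab of the 20×20×16 matrix for
the multi-compartment recovery, and 500-replicate Monte Carlo for the CRLB
and type-I-error calibrations.

## Known limitations

* Image-domain simulation: no point-spread-function, so partial-volume
  behavior at compartment boundaries — a dominant error source on real
  low-resolution CSI — is not modelled or tested.
* Pure Lorentzians with zero dead time; no first-order phase or baseline.
* The B1⁺ magnitude fit assumes the amplifier is linear in voltage and the
  pulse shape integral known; flips are restricted to (0°, 300°] by the
  initialization scan.
* Reference and main scans must share grid position and orientation
  exactly; only FOV-preserving resampling between matrix sizes is
  supported.
* In vivo B1⁺ is inherited from the phantom calibration; subject-specific
  coil loading differences are not modelled.
* The LR boundary conservatism above; and with few patients the
  intercept–slope correlation of model 3 is weakly identified (its CI is
  not reported).
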