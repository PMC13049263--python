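# dmiquant

Absolute quantification for **deuterium metabolic imaging (DMI)** at 7 T.

After a drink of [6,6-²H₂]glucose, deuterium MRSI follows the label into
glutamate/glutamine (Glx) via the TCA cycle and into lactate (Lac) via
glycolysis, alongside the HDO and glucose resonances. Reporting those signals
as absolute concentrations (mol/L) rather than ratios requires calibrating
the transmit field, the per-channel receive sensitivities and the array
combination against a reference phantom of known concentration. `dmiquant`
implements that full pipeline — and, because patient raw data are not
publicly available, ships a synthetic multi-coil CSI generator so every
stage is testable end-to-end against known ground truth.

## Method

For a spoiled steady-state CSI acquisition at flip angle θ(r) and repetition
time TR, the fitted amplitude of metabolite *m* relates to its concentration
through the saturation factor

    F(θ, TR, T1) = (1 − cos θ·e^(−TR/T1)) / (sin θ·(1 − e^(−TR/T1))),

and the phantom-replacement estimate is

    [m](r) = F_m(r)·Ŝ_m(r) / (F_P(r)·Ŝ_P(r)) · [P],

where Ŝ_P is the same quantity measured on a reference phantom of known
concentration [P] with a matched protocol. The ingredients:

* **Noise covariance Ξ** — sample covariance of a no-RF prescan.
* **Joint WSVD combination** — per voxel, spectra from all transmit-voltage
  steps are stacked into one channels × (voltages·points) matrix, whitened
  with the Cholesky factor of Ξ, and combined along the leading singular
  vector. On rank-1 data these weights equal Roemer's uniform-sensitivity
  weights w = Ξ⁻¹B1⁻ / √(B1⁻†Ξ⁻¹B1⁻) up to a phase (asserted in tests).
* **B1⁺ mapping** — per voxel, the magnitude amplitude-vs-voltage curve of a
  9-step series (25–225 V, 4 ms rectangular pulses, TR 1 s) is fitted with
  k·sin(βVB1⁺)(1−E)/(1−cos(βVB1⁺)E), β = 2π·γ(²H)·T_P·∫f.
* **B1⁻ mapping** — complex per-channel sensitivities by a closed-form
  linear solve against the fitted steady-state magnetization factors.
* **Spectral fitting** — time-domain nonlinear least squares of damped
  complex sinusoids with prior-knowledge constraints (free / fixed /
  bounded per parameter), analytic Jacobians, and Cramér–Rao lower bounds
  from the Fisher information. Linewidths fitted on the last timepoint are
  frozen for all earlier ones.
* **Quality masks** — mask #1 keeps voxels with [HDO] ≥ 5 mmol/L and HDO
  CRLB ≤ 30%; mask #2 additionally requires the delta-method CRLB of
  Lac/(Lac+Glx) ≤ 30%.
* **Kinetics & statistics** — OLS rates over the 20–90 min window, the
  glycolytic index S_Lac = d[Lac]/dt / d([Lac]+[Glx])/dt, paired Wilcoxon
  tests, AIC stepwise selection, and ML linear mixed-effects models with
  patient random intercepts/slopes plus likelihood-ratio tests.

## Worked example

Simulate a reference-phantom session, calibrate, and quantify the phantom
scan against its own calibration — the replacement identity returns the
phantom concentration exactly on noiseless data:

```python
import numpy as np
from dmiquant import GridGeometry, ProtocolParams, make_phantom_truth
from dmiquant.pipeline import run_reference_calibration, quantify_study
from dmiquant.synthetic import simulate_csi_scan

grid = GridGeometry((8, 8, 4), (220.0, 200.0, 320.0))
truth = make_phantom_truth("uniform_reference", grid, n_channels=4, seed=1)

cal_p, main_p = ProtocolParams.voltage_series(256), ProtocolParams.main_scan(256)
bundle, ref = run_reference_calibration(truth, cal_p, main_p,
                                        add_noise=False, seed=1)

sel = truth.mask() & bundle.transmit.valid_mask
err = np.abs(bundle.transmit.b1_plus[sel] - truth.b1_plus[sel]) / truth.b1_plus[sel]
print("B1+ max relative error:", err.max())

scan = simulate_csi_scan(truth, main_p, 210.0, add_noise=False)
scan.time_min = 0.0
cmap = quantify_study([scan], bundle, main_p, ref,
                      t1_table_s=truth.t1_map, metabolites=("HDO",))[0]
vals = cmap.values["HDO"][cmap.mask1]
print("recovered [HDO]: %.6f – %.6f mol/L over %d voxels"
      % (vals.min(), vals.max(), cmap.mask1.sum()))
```

Output:

```
B1+ max relative error: 3.3443874586178143e-16
recovered [HDO]: 1.140000 – 1.140000 mol/L over 72 voxels
```

The transmit field is recovered to machine precision and every masked voxel
reads exactly the 1.14 mol/L the phantom contains. With channel noise at an
amplitude SNR of 50, the B1⁺ map comes back with ≈0.1% RMS error.

The same pipeline runs from the shell:

```sh
dmiquant all --scenario brain_with_tumor --seed 1 --out run/
# -> run/calibration.h5, run/rates.csv, run/stats.json, run/roi_series.csv
```

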