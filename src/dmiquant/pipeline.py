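"""End-to-end drivers tying calibration, quantification and kinetics
together. These are what the command-line interface and the validation
studies call.
"""
from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import constants
from .calibration import (CalibrationBundle, calibrate, default_phantom_prior)
from .containers import SpectralStack
from .fitting import PriorKnowledge, fix_linewidths
from .kinetics import ROITimeSeries, fit_linear_rate, slac
from .quantify import (ConcentrationMap, ReferencePhantomSpec, SaturationTable,
                       fit_reference_amplitudes, quantify_scan)
from .synthetic import (GroundTruth, ProtocolParams, default_peaks,
                        simulate_csi_scan, simulate_prescan,
                        simulate_voltage_series)

log = logging.getLogger(__name__)


def run_reference_calibration(truth_ref: GroundTruth,
                              cal_protocol: ProtocolParams,
                              main_protocol: ProtocolParams,
                              add_noise: bool = True, seed: int = 0,
                              n_prescan_samples: int = 4096,
                              mask: Optional[np.ndarray] = None,
                              ) -> Tuple[CalibrationBundle, ReferencePhantomSpec]:
    """Simulate and process the full reference-phantom session.

    Acquires a voltage series and a no-RF prescan on the reference phantom,
    runs the calibration chain, then acquires the matched reference scan and
    fits the per-voxel reference amplitude map Ŝ_P(r).
    """
    prescan = simulate_prescan(truth_ref.noise_cov, n_prescan_samples,
                               truth_ref.n_channels, seed=seed + 1)
    series = simulate_voltage_series(truth_ref, cal_protocol,
                                     add_noise=add_noise, seed=seed)
    t1_p = truth_ref.t1_map.get("HDO", constants.REFERENCE_PHANTOM_T1_S)
    bundle = calibrate(series, prescan, cal_protocol, t1_phantom_s=t1_p,
                       mask=mask)

    ref_stack = simulate_csi_scan(truth_ref, main_protocol,
                                  main_protocol.voltages_v[0],
                                  add_noise=add_noise, seed=seed + 2)
    prior = default_phantom_prior()
    s_p = fit_reference_amplitudes(ref_stack, bundle.weights, prior,
                                   mask=bundle.weights.valid
                                   & bundle.transmit.valid_mask)
    bundle.reference_fit_amplitude = s_p
    ref_spec = ReferencePhantomSpec(
        compound="HDO",
        concentration_mol_per_l=constants.REFERENCE_PHANTOM_CONC_MOL_L,
        t1_s=t1_p, fitted_amplitude_map=s_p)
    return bundle, ref_spec


def quantify_study(stacks: Sequence[SpectralStack],
                   bundle: CalibrationBundle,
                   main_protocol: ProtocolParams,
                   ref_spec: ReferencePhantomSpec,
                   t1_table_s: Optional[Dict[str, float]] = None,
                   metabolites: Sequence[str] = ("HDO", "Glc", "Glx", "Lac"),
                   mask: Optional[np.ndarray] = None,
                   ) -> List[ConcentrationMap]:
    """Quantify a longitudinal series of main scans.

    The last (highest-label) timepoint is fitted with free linewidths; the
    resulting per-voxel linewidths are then fixed in the prior used for all
    earlier timepoints.
    """
    sat = SaturationTable.from_transmit(bundle.transmit, main_protocol,
                                        t1_table_s)
    prior = PriorKnowledge.from_peaks(default_peaks(metabolites))
    prefit: Dict[tuple, object] = {}
    last_map = quantify_scan(stacks[-1], bundle.weights, bundle.transmit,
                             prior, sat, ref_spec, mask=mask, prefit=prefit)
    last_map.meta["time_min"] = stacks[-1].time_min

    prior_map = {}
    for vox, fit in prefit.items():
        if fit.converged:
            prior_map[vox] = fix_linewidths(prior, fit)

    maps = []
    for stack in stacks[:-1]:
        cmap = quantify_scan(stack, bundle.weights, bundle.transmit, prior,
                             sat, ref_spec, mask=mask, prior_map=prior_map)
        cmap.meta["time_min"] = stack.time_min
        maps.append(cmap)
    maps.append(last_map)
    return maps


def rates_table(series: Sequence[ROITimeSeries],
                metabolites: Sequence[str] = ("Glx", "Lac"),
                window: Tuple[float, float] = constants.RATE_WINDOW_MIN
                ) -> pd.DataFrame:
    """Per (subject, region) kinetic rates and S_Lac from ROI series."""
    rows = []
    for s in series:
        fits = {}
        for m in metabolites:
            if m not in s.conc_mmol_l:
                continue
            fits[m] = fit_linear_rate(s.time_min, s.conc_mmol_l[m], window)
            rows.append({"subject": s.subject_id, "region": s.region,
                         "metabolite": m,
                         "rate_umol_l_min": fits[m].slope_umol_l_min,
                         "se_umol_l_min": fits[m].se_umol_l_min,
                         "ci_lo": fits[m].ci95_umol_l_min[0],
                         "ci_hi": fits[m].ci95_umol_l_min[1],
                         "n_points": fits[m].n_points})
        if "Lac" in fits and "Glx" in fits:
            rows.append({"subject": s.subject_id, "region": s.region,
                         "metabolite": "S_Lac",
                         "rate_umol_l_min": slac(fits["Lac"].slope_umol_l_min,
                                                 fits["Glx"].slope_umol_l_min),
                         "se_umol_l_min": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan,
                         "n_points": fits["Lac"].n_points})
    return pd.DataFrame(rows)


def concentration_table(cmap: ConcentrationMap) -> pd.DataFrame:
    """Per-voxel long-format concentration table (masked voxels only)."""
    rows = []
    for ix, iy, iz in np.argwhere(cmap.mask1):
        for m, vol in cmap.values.items():
            rows.append({"ix": ix, "iy": iy, "iz": iz, "metabolite": m,
                         "conc_mol_l": vol[ix, iy, iz],
                         "crlb_percent": cmap.crlb_percent[m][ix, iy, iz],
                         "mask1": bool(cmap.mask1[ix, iy, iz]),
                         "mask2": bool(cmap.mask2[ix, iy, iz])})
    return pd.DataFrame(rows)
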