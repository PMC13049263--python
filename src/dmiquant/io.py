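"""File formats: the HDF5 fixture container, calibration bundles, NIfTI
maps and ROI labels, YAML run configuration.

The fixture container replaces vendor raw data with a documented schema
(version 1):

    attrs: schema_version, seed, scenario, protocol_* scalars,
           protocol_voltages_v, grid_matrix, grid_fov_mm, grid_offset_mm
    /acquisitions/NNN/fids   complex (nx,ny,nz,nchan,npts); attrs
                             voltage_v, time_min (NaN when absent)
    /prescan                 complex (nchan, nsamples), no-RF noise
    /truth/*                 optional ground-truth arrays (b1_plus, k_scale,
                             b1_minus, noise_cov, region_labels,
                             conc_<metabolite>; attrs t1_<metabolite>)

An adapter for scanner raw formats would produce the same container.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import nibabel as nib
import numpy as np
import yaml

from . import constants
from .calibration import (CalibrationBundle, CoilWeights, NoiseCovariance,
                          ReceiveMap, TransmitMap)
from .containers import SpectralStack
from .grids import GridGeometry
from .synthetic import GroundTruth, ProtocolParams

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Container schema version or layout mismatch."""


def _write_grid_attrs(obj, grid: GridGeometry) -> None:
    obj.attrs["grid_matrix"] = np.asarray(grid.matrix, dtype=np.int64)
    obj.attrs["grid_fov_mm"] = np.asarray(grid.fov_mm, dtype=float)
    obj.attrs["grid_offset_mm"] = np.asarray(grid.offset_mm, dtype=float)


def _read_grid_attrs(obj) -> GridGeometry:
    return GridGeometry(tuple(int(v) for v in obj.attrs["grid_matrix"]),
                        tuple(float(v) for v in obj.attrs["grid_fov_mm"]),
                        tuple(float(v) for v in obj.attrs["grid_offset_mm"]))


def write_fixture(path, stacks: Sequence[SpectralStack],
                  protocol: ProtocolParams, prescan: np.ndarray,
                  truth: Optional[GroundTruth] = None,
                  seed: Optional[int] = None, scenario: str = "") -> None:
    """Write acquisitions + prescan (+ optional truth) to a fixture file."""
    prescan = np.asarray(prescan)
    if isinstance(prescan, np.ndarray) and prescan.ndim != 2:
        prescan = prescan.reshape(prescan.shape[-2], -1) if prescan.ndim > 2 \
            else prescan
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["seed"] = -1 if seed is None else int(seed)
        f.attrs["scenario"] = scenario
        f.attrs["protocol_tr_s"] = protocol.tr_s
        f.attrs["protocol_pulse_duration_s"] = protocol.pulse_duration_s
        f.attrs["protocol_pulse_shape_integral"] = protocol.pulse_shape_integral
        f.attrs["protocol_spectral_bw_hz"] = protocol.spectral_bw_hz
        f.attrs["protocol_n_samples"] = protocol.n_samples
        f.attrs["protocol_gamma_hz_per_t"] = protocol.gamma_hz_per_t
        f.attrs["protocol_voltages_v"] = np.asarray(protocol.voltages_v)
        _write_grid_attrs(f, stacks[0].grid)
        acq = f.create_group("acquisitions")
        for i, s in enumerate(stacks):
            g = acq.create_group(f"{i:03d}")
            g.create_dataset("fids", data=s.fids)
            g.attrs["voltage_v"] = np.nan if s.voltage_v is None else s.voltage_v
            g.attrs["time_min"] = np.nan if s.time_min is None else s.time_min
            g.attrs["dwell_s"] = s.dwell_s
        f.create_dataset("prescan", data=prescan)
        if truth is not None:
            tg = f.create_group("truth")
            tg.create_dataset("b1_plus", data=truth.b1_plus)
            tg.create_dataset("k_scale", data=truth.k_scale)
            tg.create_dataset("b1_minus", data=truth.b1_minus)
            tg.create_dataset("noise_cov", data=truth.noise_cov)
            tg.create_dataset("region_labels", data=truth.region_labels)
            for m, c in truth.concentrations.items():
                tg.create_dataset(f"conc_{m}", data=c)
                tg.attrs[f"t1_{m}"] = truth.t1_map[m]


def read_fixture(path) -> Tuple[List[SpectralStack], ProtocolParams,
                                np.ndarray, Optional[GroundTruth]]:
    """Read a fixture container.

    Returns (stacks, protocol, prescan, truth-or-None). Raises
    :class:`SchemaError` on unsupported schema versions and a KeyError
    naming the dataset when a required one is missing.
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported fixture schema version {version}; "
                f"this reader supports version {SCHEMA_VERSION}")
        if "prescan" not in f:
            raise KeyError("fixture is missing required dataset '/prescan'")
        if "acquisitions" not in f:
            raise KeyError("fixture is missing required group '/acquisitions'")
        protocol = ProtocolParams(
            tr_s=float(f.attrs["protocol_tr_s"]),
            pulse_duration_s=float(f.attrs["protocol_pulse_duration_s"]),
            pulse_shape_integral=float(f.attrs["protocol_pulse_shape_integral"]),
            voltages_v=tuple(f.attrs["protocol_voltages_v"]),
            spectral_bw_hz=float(f.attrs["protocol_spectral_bw_hz"]),
            n_samples=int(f.attrs["protocol_n_samples"]),
            gamma_hz_per_t=float(f.attrs["protocol_gamma_hz_per_t"]))
        grid = _read_grid_attrs(f)
        stacks = []
        for name in sorted(f["acquisitions"]):
            g = f["acquisitions"][name]
            volt = float(g.attrs["voltage_v"])
            tmin = float(g.attrs["time_min"])
            stacks.append(SpectralStack(
                fids=g["fids"][()], grid=grid,
                dwell_s=float(g.attrs["dwell_s"]),
                voltage_v=None if np.isnan(volt) else volt,
                time_min=None if np.isnan(tmin) else tmin))
        prescan = f["prescan"][()]
        truth = None
        if "truth" in f:
            tg = f["truth"]
            conc = {}
            t1 = {}
            for key in tg:
                if key.startswith("conc_"):
                    m = key[len("conc_"):]
                    conc[m] = tg[key][()]
                    t1[m] = float(tg.attrs[f"t1_{m}"])
            truth = GroundTruth(
                grid=grid, b1_plus=tg["b1_plus"][()],
                k_scale=tg["k_scale"][()], b1_minus=tg["b1_minus"][()],
                noise_cov=tg["noise_cov"][()],
                concentrations=conc, t1_map=t1,
                region_labels=tg["region_labels"][()],
                seed=int(f.attrs["seed"]),
                scenario=str(f.attrs.get("scenario", "")))
    return stacks, protocol, prescan, truth


def write_calibration(path, bundle: CalibrationBundle) -> None:
    """Write a calibration bundle (HDF5): B1+, k, B1−, weights, Ξ."""
    grid = bundle.transmit.grid
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        _write_grid_attrs(f, grid)
        f.create_dataset("b1_plus", data=bundle.transmit.b1_plus)
        f.create_dataset("k_scale", data=bundle.transmit.k_scale)
        f.create_dataset("fit_residual", data=bundle.transmit.fit_residual)
        f.create_dataset("transmit_valid", data=bundle.transmit.valid_mask)
        f.create_dataset("b1_minus", data=bundle.receive.b1_minus)
        f.create_dataset("phase_reference", data=bundle.receive.phase_reference)
        f.create_dataset("weights", data=bundle.weights.w)
        f.create_dataset("weights_valid", data=bundle.weights.valid)
        f.create_dataset("xi", data=bundle.xi.xi)
        f.attrs["xi_n_samples"] = bundle.xi.n_samples_used
        if bundle.reference_fit_amplitude is not None:
            f.create_dataset("reference_fit_amplitude",
                             data=bundle.reference_fit_amplitude)


def read_calibration(path) -> CalibrationBundle:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported calibration schema version {version}")
        grid = _read_grid_attrs(f)
        transmit = TransmitMap(b1_plus=f["b1_plus"][()],
                               k_scale=f["k_scale"][()],
                               fit_residual=f["fit_residual"][()],
                               valid_mask=f["transmit_valid"][()].astype(bool),
                               grid=grid)
        receive = ReceiveMap(b1_minus=f["b1_minus"][()],
                             phase_reference=f["phase_reference"][()],
                             valid_mask=transmit.valid_mask, grid=grid)
        weights = CoilWeights(w=f["weights"][()],
                              valid=f["weights_valid"][()].astype(bool),
                              grid=grid)
        xi = NoiseCovariance(xi=f["xi"][()],
                             n_samples_used=int(f.attrs["xi_n_samples"]))
        ref_amp = (f["reference_fit_amplitude"][()]
                   if "reference_fit_amplitude" in f else None)
    return CalibrationBundle(xi=xi, transmit=transmit, receive=receive,
                             weights=weights, reference_fit_amplitude=ref_amp)


def write_nifti_map(field: np.ndarray, grid: GridGeometry, path) -> None:
    """Write a 3-D (or 3-D + trailing) field as float32 NIfTI-1; the affine
    encodes voxel size FOV/matrix in mm with centers at (i+0.5)Δ − FOV/2."""
    if field.shape[:3] != tuple(grid.matrix):
        raise ValueError("field shape does not match grid")
    img = nib.Nifti1Image(np.asarray(field, dtype=np.float32), grid.affine())
    nib.save(img, str(path))


def read_nifti_map(path) -> Tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def read_roi_labels(path) -> np.ndarray:
    """Load an ROI label volume; labels must be non-negative integers."""
    data, _ = read_nifti_map(path)
    rounded = np.round(data)
    if not np.allclose(data, rounded, atol=1e-6) or np.any(rounded < 0):
        raise ValueError("ROI labels must be non-negative integers")
    return rounded.astype(np.int32)


@dataclass
class RunConfig:
    """Pipeline run configuration with the study thresholds as defaults."""

    scan: Optional[str] = None
    prescan: Optional[str] = None
    calibration: Optional[str] = None
    rois: Optional[str] = None
    subjects: Optional[str] = None
    output_dir: str = "."
    seed: int = 0
    ref_conc_mol_l: float = constants.REFERENCE_PHANTOM_CONC_MOL_L
    ref_t1_s: float = constants.REFERENCE_PHANTOM_T1_S
    t1_table_s: Dict[str, float] = field(
        default_factory=lambda: dict(constants.T1_LITERATURE_S))
    hdo_min_mol_l: float = constants.MASK_HDO_MIN_MOL_L
    hdo_crlb_max_percent: float = constants.MASK_HDO_CRLB_MAX_PERCENT
    ratio_crlb_max_percent: float = constants.MASK_RATIO_CRLB_MAX_PERCENT
    window_min: Tuple[float, float] = constants.RATE_WINDOW_MIN

    def __post_init__(self):
        if self.hdo_min_mol_l <= 0 or self.hdo_crlb_max_percent <= 0 \
                or self.ratio_crlb_max_percent <= 0:
            raise ValueError("thresholds must be positive")
        if not self.window_min[0] < self.window_min[1]:
            raise ValueError("window start must precede window end")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "window_min" in data:
            data["window_min"] = tuple(data["window_min"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
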