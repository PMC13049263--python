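"""In-memory containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grids import GridGeometry


@dataclass
class SpectralStack:
    """One CSI acquisition: per-voxel, per-channel complex FIDs.

    ``fids`` has shape (nx, ny, nz, n_channels, n_points). The frequency-
    domain view is obtained with :meth:`spectra`. ``voltage_v`` tags a
    voltage-series member; ``time_min`` tags a longitudinal timepoint.
    """

    fids: np.ndarray
    grid: GridGeometry
    dwell_s: float
    voltage_v: Optional[float] = None
    time_min: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fids = np.asarray(self.fids, dtype=np.complex128)
        if self.fids.ndim != 5:
            raise ValueError(
                f"fids must be 5-D (nx, ny, nz, nchan, npts), got shape {self.fids.shape}")
        if tuple(self.fids.shape[:3]) != tuple(self.grid.matrix):
            raise ValueError(
                f"fids spatial shape {self.fids.shape[:3]} does not match "
                f"grid matrix {self.grid.matrix}")
        if self.dwell_s <= 0:
            raise ValueError("dwell_s must be positive")

    @property
    def n_channels(self) -> int:
        return self.fids.shape[3]

    @property
    def n_points(self) -> int:
        return self.fids.shape[4]

    def time_axis_s(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_s

    def spectra(self) -> np.ndarray:
        """FFT of the FIDs along time (same shape, frequency-ordered with
        fftshift so index 0 is −BW/2)."""
        return np.fft.fftshift(np.fft.fft(self.fids, axis=-1), axes=-1)

    def frequency_axis_hz(self) -> np.ndarray:
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_s))
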