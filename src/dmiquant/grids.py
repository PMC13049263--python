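"""CSI grid geometry.

Convention: 0-based voxel indices; voxel centers at (i + 0.5)·Δ − FOV/2 +
offset in each axis, with Δ = FOV/matrix; RAS-like diagonal affine.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a 3D CSI voxel grid."""

    matrix: tuple[int, int, int]
    fov_mm: tuple[float, float, float]
    offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.matrix) != 3 or any(int(n) <= 0 for n in self.matrix):
            raise ValueError(f"matrix must be 3 positive integers, got {self.matrix}")
        if len(self.fov_mm) != 3 or any(f <= 0 for f in self.fov_mm):
            raise ValueError(f"fov_mm must be 3 positive reals, got {self.fov_mm}")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.asarray(self.fov_mm, float) / np.asarray(self.matrix, float)

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.matrix[axis]
        d = self.fov_mm[axis] / n
        return (np.arange(n) + 0.5) * d - self.fov_mm[axis] / 2.0 + self.offset_mm[axis]

    def center_coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij indexing) of voxel-center coordinates."""
        return np.meshgrid(*(self.axis_centers_mm(a) for a in range(3)), indexing="ij")

    def affine(self) -> np.ndarray:
        """NIfTI affine mapping voxel index -> mm coordinate of the center."""
        aff = np.eye(4)
        d = self.voxel_size_mm
        for a in range(3):
            aff[a, a] = d[a]
            aff[a, 3] = 0.5 * d[a] - self.fov_mm[a] / 2.0 + self.offset_mm[a]
        return aff

    def same_fov(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (np.allclose(self.fov_mm, other.fov_mm, atol=tol)
                and np.allclose(self.offset_mm, other.offset_mm, atol=tol))

    def __eq__(self, other):
        if not isinstance(other, GridGeometry):
            return NotImplemented
        return (self.matrix == tuple(other.matrix)
                and np.allclose(self.fov_mm, other.fov_mm)
                and np.allclose(self.offset_mm, other.offset_mm))

    def __hash__(self):
        return hash((self.matrix, tuple(round(f, 9) for f in self.fov_mm)))
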