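"""Reconstructed-volume container.

A :class:`ReconVolume` is a 3D intensity grid ordered (slice, row, col) =
(z, y, x) with voxel spacings in mm and an origin giving the world (xyz)
position of voxel (0, 0, 0).  Row 0 adjoins the chest-wall edge of the
field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReconVolume"]


@dataclass
class ReconVolume:
    intensities: np.ndarray  # (nz, ny, nx)
    spacing: tuple[float, float, float]  # (dz, dy, dx) mm
    origin: tuple[float, float, float]  # xyz mm of voxel (0, 0, 0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D (slice,row,col) array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacings must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    # -- coordinate helpers ----------------------------------------------

    @property
    def z_positions(self) -> np.ndarray:
        """World z (mm) of every slice centre."""
        return self.origin[2] + np.arange(self.shape[0]) * self.spacing[0]

    @property
    def y_positions(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[1]) * self.spacing[1]

    @property
    def x_positions(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[2]) * self.spacing[2]

    def world_to_index(self, xyz) -> np.ndarray:
        """Fractional (slice, row, col) indices of world points (n, 3) xyz."""
        p = np.atleast_2d(np.asarray(xyz, dtype=float))
        dz, dy, dx = self.spacing
        x0, y0, z0 = self.origin
        idx = np.column_stack([
            (p[:, 2] - z0) / dz,
            (p[:, 1] - y0) / dy,
            (p[:, 0] - x0) / dx,
        ])
        return idx if np.asarray(xyz).ndim == 2 else idx[0]

    def index_to_world(self, izyx) -> np.ndarray:
        """World xyz (mm) of fractional (slice, row, col) indices."""
        p = np.atleast_2d(np.asarray(izyx, dtype=float))
        dz, dy, dx = self.spacing
        x0, y0, z0 = self.origin
        w = np.column_stack([
            x0 + p[:, 2] * dx,
            y0 + p[:, 1] * dy,
            z0 + p[:, 0] * dz,
        ])
        return w if np.asarray(izyx).ndim == 2 else w[0]

    def slice_nearest(self, z: float) -> int:
        """Index of the slice whose centre is nearest world z (mm)."""
        return int(np.clip(round((z - self.origin[2]) / self.spacing[0]),
                           0, self.shape[0] - 1))
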