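"""Voxel grids and image volumes.

The image ``x`` lives on a regular 3D lattice with physical spacing in mm.
Conventions: 0-based indices, voxel-center sampling, right-handed frame with
z along the rotation axis; ``origin`` is the mm offset of the grid *center*
from the isocenter (the rotation axis passes through x = y = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["VolumeGrid", "Volume"]


@dataclass(frozen=True)
class VolumeGrid:
    """Regular voxel lattice: counts, mm spacings and center offset."""

    n_x: int
    n_y: int
    n_z: int
    spacing_x: float = 1.0
    spacing_y: float = 1.0
    spacing_z: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_z) < 1:
            raise ValidationError("voxel counts must be >= 1")
        if min(self.spacing_x, self.spacing_y, self.spacing_z) <= 0:
            raise ValidationError("voxel spacings must be > 0")
        if len(self.origin) != 3:
            raise ValidationError("origin must be a 3-vector (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_x, self.n_y, self.n_z)

    @property
    def spacing(self) -> np.ndarray:
        return np.array([self.spacing_x, self.spacing_y, self.spacing_z])

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        sp = self.spacing[axis]
        return self.origin[axis] + (np.arange(n) - (n - 1) / 2.0) * sp

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to mm positions (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        n = np.array(self.shape, dtype=float)
        return np.asarray(self.origin) + (ijk - (n - 1) / 2.0) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_world` (fractional indices)."""
        xyz = np.asarray(xyz, dtype=float)
        n = np.array(self.shape, dtype=float)
        return (xyz - np.asarray(self.origin)) / self.spacing + (n - 1) / 2.0

    def meshgrid_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate arrays broadcastable to the grid shape."""
        cx = self.axis_coords(0)[:, None, None]
        cy = self.axis_coords(1)[None, :, None]
        cz = self.axis_coords(2)[None, None, :]
        return cx, cy, cz


@dataclass
class Volume:
    """A 3D attenuation image (mm^-1) on a :class:`VolumeGrid`.

    ``data`` is indexed ``[i, j, k]`` along (x, y, z).
    """

    data: np.ndarray
    grid: VolumeGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.shape:
            raise ValidationError(
                f"volume data shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: VolumeGrid) -> "Volume":
        return cls(np.zeros(grid.shape), grid)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.grid)
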