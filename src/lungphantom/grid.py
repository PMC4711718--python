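"""Voxel lattice container shared by CT volumes, masks, and oxygenation maps.

World coordinates use the voxel-center convention: the center of voxel
index ``i`` (0-based) sits at ``origin + i * spacing`` (mm).  Arrays are
indexed ``values[i, j, k]`` in the same axis order as ``shape``, ``spacing``
and ``origin``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class LungPhantomError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(LungPhantomError):
    """A parameter set violates its stated invariants."""


class PreconditionError(LungPhantomError):
    """An operation was called on inputs that do not satisfy its contract."""


class FormatError(LungPhantomError):
    """A file could not be read or written as a geometric volume."""


@dataclass
class VoxelGrid:
    """A 3D scalar lattice with physical spacing and origin.

    Parameters
    ----------
    values
        Scalar array of shape ``shape``.
    spacing
        Positive voxel size per axis, in mm.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise InvalidConfigurationError(
                f"VoxelGrid requires a 3D array, got ndim={self.values.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise InvalidConfigurationError(f"spacing must be positive: {self.spacing}")
        if any(n < 1 for n in self.values.shape):
            raise InvalidConfigurationError(f"degenerate shape: {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def like(self, values: np.ndarray) -> "VoxelGrid":
        """A new grid with the same geometry and different values."""
        return VoxelGrid(values, self.spacing, self.origin)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.values.copy(), self.spacing, self.origin)

    # ---- coordinate transforms -------------------------------------------------

    def index_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of voxel centers for (possibly fractional) indices."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, position) -> np.ndarray:
        """Continuous voxel index of a world position (mm)."""
        pos = np.asarray(position, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_to_voxel(self, position) -> tuple[int, int, int]:
        """Nearest voxel index of a world position; raises if outside the grid."""
        idx = np.rint(self.world_to_index(position)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise PreconditionError(f"position {position} outside grid {self.shape}")
        return tuple(int(i) for i in idx)

    def contains(self, position) -> bool:
        idx = np.rint(self.world_to_index(position))
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers (for meshgrid use)."""
        return tuple(  # type: ignore[return-value]
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


def zeros_like_grid(shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), dtype=float) -> VoxelGrid:
    return VoxelGrid(np.zeros(tuple(shape), dtype=dtype), spacing, origin)
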