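"""Voxel grids and dose volumes.

The reconstruction volume is a regular 3D voxel grid with voxel-center
sampling: voxel ``(0, 0, 0)`` is centered at ``origin`` and voxel
``(i, j, k)`` at ``origin + index * voxel_size``.  Axes are right-handed
(x, y, z); by default the grid is centered on the machine isocenter, so a
symmetric field produces an exactly symmetric dose.  The default study
geometry is a 10 cm cube split into 100x100x100 voxels of 1 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "DoseVolume", "make_grid"]


def _as_triple(value, name: str, dtype=float) -> tuple:
    arr = np.asarray(value)
    if arr.ndim == 0:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a scalar or a length-3 sequence, got {value!r}")
    return tuple(dtype(v) for v in arr)


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid with physical geometry in millimetres.

    Parameters
    ----------
    shape : (nx, ny, nz)
        Number of voxels per axis; every entry must be >= 1.
    voxel_size : (dx, dy, dz)
        Voxel edge lengths in mm; strictly positive.
    origin : (x0, y0, z0)
        Physical coordinate (mm) of the *center* of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "shape", _as_triple(self.shape, "shape", int))
        object.__setattr__(self, "voxel_size", _as_triple(self.voxel_size, "voxel_size"))
        object.__setattr__(self, "origin", _as_triple(self.origin, "origin"))
        if any(n < 1 for n in self.shape):
            raise ValueError(f"grid shape must be >= 1 per axis, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be > 0 per axis, got {self.voxel_size}")
        if not all(np.isfinite(self.origin)):
            raise ValueError(f"origin must be finite, got {self.origin}")

    @property
    def n_voxels(self) -> int:
        """Total voxel count m."""
        return int(np.prod(self.shape))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent (mm) per axis, outer face to outer face."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer-face bounding box ``(lo, hi)`` in mm."""
        o = np.asarray(self.origin)
        v = np.asarray(self.voxel_size)
        n = np.asarray(self.shape)
        lo = o - v / 2.0
        hi = o + (n - 1) * v + v / 2.0
        return lo, hi

    @property
    def center(self) -> np.ndarray:
        """Physical center of the grid volume (mm)."""
        lo, hi = self.bounds
        return (lo + hi) / 2.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.voxel_size[axis]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-center coordinate arrays (X, Y, Z)."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def index_to_physical(self, index) -> np.ndarray:
        """Physical coordinate (mm) of voxel-center ``index`` (may be fractional)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.voxel_size)

    def physical_to_index(self, point) -> np.ndarray:
        """Fractional voxel index of a physical point (mm); inverse of index_to_physical."""
        pt = np.asarray(point, dtype=float)
        return (pt - np.asarray(self.origin)) / np.asarray(self.voxel_size)


def make_grid(shape, voxel_size, origin=None) -> GridSpec:
    """Create a :class:`GridSpec`; with ``origin=None`` the grid is centered
    on the isocenter (physical center at the coordinate origin).

    >>> g = make_grid((100, 100, 100), 1.0)
    >>> g.extent
    (100.0, 100.0, 100.0)
    """
    shape = _as_triple(shape, "shape", int)
    voxel_size = _as_triple(voxel_size, "voxel_size")
    if origin is None:
        origin = tuple(-(n - 1) * v / 2.0 for n, v in zip(shape, voxel_size))
    return GridSpec(shape=shape, voxel_size=voxel_size, origin=origin)


@dataclass
class DoseVolume:
    """A nonnegative 3D dose field on a :class:`GridSpec`.

    Values are in Gy, or arbitrary linear units before calibration.
    """

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def max(self) -> float:
        return float(self.values.max())

    def ravel(self) -> np.ndarray:
        """Flat dose vector D (C order), as consumed by the forward model."""
        return self.values.ravel()

    def with_values(self, values: np.ndarray) -> "DoseVolume":
        return DoseVolume(grid=self.grid, values=values)

    def __add__(self, other: "DoseVolume") -> "DoseVolume":
        if not isinstance(other, DoseVolume):
            return NotImplemented
        if other.grid != self.grid:
            raise ValueError("cannot add dose volumes on different grids")
        return DoseVolume(self.grid, self.values + other.values)

    def __mul__(self, scalar: float) -> "DoseVolume":
        return DoseVolume(self.grid, self.values * float(scalar))

    __rmul__ = __mul__
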