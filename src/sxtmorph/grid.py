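"""Voxel-grid container shared by every pipeline stage.

All physical quantities are carried in micrometres: voxel edges in µm,
linear attenuation coefficients (LAC) in µm^-1.  A grid knows its unit
tag; conversions between tags are explicit operations (see
:mod:`sxtmorph.lac`), never silent relabelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np


class Units(str, Enum):
    """Physical interpretation of the voxel values."""

    ABSORBANCE = "absorbance"     # per-voxel natural-log optical density
    LAC = "LAC_per_um"            # linear attenuation coefficient, µm^-1
    TRANSMISSION = "transmission"  # I/I0 along a ray, in (0, 1]
    LABEL = "label"               # non-negative integer labels


def _as_triple(v) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError(f"voxel size must be scalar or length-3, got {v!r}")
    return tuple(arr)


@dataclass
class VoxelGrid3D:
    """A 3D scalar or label volume with voxel size and unit metadata.

    Axis order is (z, y, x), indices are 0-based, and the centre of voxel
    ``(i, j, k)`` sits at physical position ``origin + (i+0.5)*voxel_size``.

    Parameters
    ----------
    data:
        3D array.  Scalar grids are stored as float, label grids as
        integers.
    voxel_size:
        Edge length(s) in µm; a scalar is broadcast to an isotropic
        triple ``(z, y, x)``.
    units:
        One of :class:`Units` (or its string value).
    origin:
        Physical coordinate of voxel (0, 0, 0) in µm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    units: Units
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise ValueError(f"degenerate shape {self.data.shape}")
        self.voxel_size = _as_triple(self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size}")
        self.units = Units(self.units)
        self.origin = _as_triple(self.origin)
        self._validate_values()

    def _validate_values(self) -> None:
        if self.units is Units.LABEL:
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ValueError("label grids must hold integers")
            if self.data.min(initial=0) < 0:
                raise ValueError("label grids must be non-negative")
        elif self.units is Units.TRANSMISSION:
            if self.data.min() <= 0 or self.data.max() > 1:
                raise ValueError("transmission values must lie in (0, 1]")
        elif self.units is Units.LAC:
            if self.data.min() < 0:
                raise ValueError("LAC values must be non-negative")

    # -- convenience -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.voxel_size))

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.voxel_size)) == 1

    def with_data(self, data: np.ndarray, units: Units | str | None = None) -> "VoxelGrid3D":
        """New grid sharing this grid's geometry with different values."""
        return replace(self, data=data, units=Units(units) if units is not None else self.units)

    def physical_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinate axes (z, y, x) in µm."""
        return tuple(
            self.origin[ax] + (np.arange(self.shape[ax]) + 0.5) * self.voxel_size[ax]
            for ax in range(3)
        )
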