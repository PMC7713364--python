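"""Reading and writing volumes, configs, and morphometry reports.

Volumes travel as MRC2014 (preferred for tomography) or multi-page TIFF
stacks.  MRC carries the voxel size in its pixel-spacing header fields;
TIFF dialects disagree on resolution tags, so TIFF input requires an
explicit voxel size — silent unit errors are worse than one extra
argument.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile
import yaml

from .grid import Units, VoxelGrid3D


class VolumeFormatError(RuntimeError):
    """The file could not be read as an MRC2014 or TIFF volume."""


class VolumeMetadataError(RuntimeError):
    """Required metadata (voxel size, units) is missing or contradictory."""


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}
_MRC_SUFFIXES = {".mrc", ".rec", ".st"}


def read_volume(
    path: str | Path,
    units: Units | str,
    voxel_size_override: float | Sequence[float] | None = None,
) -> VoxelGrid3D:
    """Read an MRC2014 or TIFF-stack volume into a :class:`VoxelGrid3D`.

    Parameters
    ----------
    path:
        Input file; format resolved from the suffix.
    units:
        Physical unit tag for the voxel values.  Units are declared by
        the caller, never sniffed from the data.
    voxel_size_override:
        Voxel edge in µm.  Optional for MRC (header pixel spacing is
        used), mandatory for TIFF.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _MRC_SUFFIXES:
        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:  # pragma: no cover - backend-specific message
            raise VolumeFormatError(f"cannot read MRC volume {path}: {exc}") from exc
        data = sitk.GetArrayFromImage(img)
        # ITK spacing order is (x, y, z); grids are (z, y, x)
        header_vs = tuple(reversed(img.GetSpacing()))
        voxel_size = voxel_size_override if voxel_size_override is not None else header_vs
        if voxel_size is None or np.any(np.asarray(voxel_size) <= 0):
            raise VolumeMetadataError(f"no usable voxel size in {path} header")
    elif suffix in _TIFF_SUFFIXES:
        try:
            data = tifffile.imread(str(path))
        except Exception as exc:
            raise VolumeFormatError(f"cannot read TIFF stack {path}: {exc}") from exc
        if voxel_size_override is None:
            raise VolumeMetadataError(
                f"TIFF input {path} requires an explicit voxel size (µm); "
                "resolution tags are not trusted"
            )
        voxel_size = voxel_size_override
    else:
        raise VolumeFormatError(f"unsupported volume format: {path.suffix!r}")

    if data.ndim == 2:
        data = data[None]
    units = Units(units)
    if units is Units.LABEL:
        data = np.ascontiguousarray(data).astype(np.int32, copy=False)
    return VoxelGrid3D(data=data, voxel_size=voxel_size, units=units)


def write_volume(grid: VoxelGrid3D, path: str | Path) -> Path:
    """Write a grid to MRC2014 or TIFF; the format follows the suffix.

    MRC stores the voxel size (µm) in the pixel-spacing header; label
    grids are written as 16-bit integers, scalar grids as float32.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if grid.units is Units.LABEL:
        out = grid.data.astype(np.uint16 if grid.data.max(initial=0) < 2**16 else np.int32)
    else:
        out = grid.data.astype(np.float32)
    if suffix in _MRC_SUFFIXES:
        img = sitk.GetImageFromArray(out)
        img.SetSpacing(tuple(reversed(grid.voxel_size)))
        sitk.WriteImage(img, str(path))
    elif suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(str(path), out, photometric="minisblack")
    else:
        raise VolumeFormatError(f"unsupported volume format: {path.suffix!r}")
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable pipeline parameters.

    All lengths in µm, attenuation in µm^-1, volumes in µm³.  Keys in a
    YAML config may carry an ``_nm`` suffix and are converted to µm when
    parsed.
    """

    lac_window: tuple[float, float] = (0.20, 0.35)
    size_window: tuple[float, float] = (0.02, 1.0)
    denoise_sigma: float = 1.0         # voxels; Gaussian denoise before thresholding
    opening_radius: int = 1            # voxels; 0 disables morphological opening
    fill_holes: bool = True            # include enclosed low-LAC interiors in objects
    feature_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)  # voxels
    n_trees: int = 50
    mesh_smoothing_sigma: float = 1.0  # voxels, applied before isosurfacing
    min_hole_voxels: int = 8           # speckle below 35-nm optics at 20-nm voxels
    report_decimals: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lac_window
        if not lo < hi:
            raise ValueError(f"lac_window low must be < high, got {self.lac_window}")
        vmin, vmax = self.size_window
        if not vmin < vmax:
            raise ValueError(f"size_window min must be < max, got {self.size_window}")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in raw.items():
            if key.endswith("_nm"):
                key = key[:-3]
                value = np.asarray(value, dtype=float) / 1000.0
                value = value.tolist()
            if key not in known:
                raise ValueError(f"unknown config field {key!r}")
            fld = next(f for f in dataclasses.fields(cls) if f.name == key)
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

#: Column order of the per-object table (one row per mitochondrion).
REPORT_COLUMNS = [
    "object_id",
    "length_um",
    "width_um",
    "aspect_ratio",
    "volume_total_um3",
    "volume_cristae_um3",
    "volume_matrix_um3",
    "volfrac_cristae_pct",
    "volfrac_matrix_pct",
    "sa_cristae_um2",
    "sa_matrix_um2",
    "mean_lac_per_um",
    "mci",
]


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Normalise morphometry records (dataclasses or dicts) to a DataFrame."""
    rows = []
    for rec in records:
        d = dataclasses.asdict(rec) if dataclasses.is_dataclass(rec) else dict(rec)
        rows.append({c: d.get(c) for c in REPORT_COLUMNS})
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(
    records: Sequence,
    path: str | Path,
    format: str = "csv",
    decimals: int = 2,
) -> Path:
    """Serialise per-object morphometry to CSV or JSON.

    Numeric values are rounded to ``decimals`` places in the written
    file (full precision stays with the in-memory records).  An empty
    record list produces a header-only file and a warning.
    """
    path = Path(path)
    frame = records_to_frame(records)
    if frame.empty:
        warnings.warn(f"writing header-only report to {path}: no records", stacklevel=2)
    numeric = frame.select_dtypes(include="number").columns.difference(["object_id"])
    frame[numeric] = frame[numeric].round(decimals)
    if format == "csv":
        frame.to_csv(path, index=False, float_format=f"%.{decimals}f")
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path
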