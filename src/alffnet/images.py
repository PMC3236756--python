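"""In-memory volume containers and NIfTI / phenotype I/O.

The containers are thin, grid-aware wrappers around numpy arrays:
:class:`ScalarMap` for one value per voxel and :class:`Bold4D` for a BOLD
time series (time is axis 0).  NIfTI reading/writing goes through nibabel;
volumes are written uncompressed (.nii) so outputs are byte-deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GridMismatchError, ParameterError, ValidationError
from .grid import VolumeGrid

__all__ = [
    "ScalarMap",
    "Bold4D",
    "load_grid",
    "load_scalar",
    "load_bold",
    "save_scalar",
    "save_bold",
    "read_phenotype",
    "extract_roi_mean",
]

MIN_TIMEPOINTS = 8

REQUIRED_PHENOTYPE_COLUMNS = ("subject_id", "center", "sex", "age")
OPTIONAL_PHENOTYPE_COLUMNS = ("tcv", "gmv")


@dataclass(frozen=True)
class ScalarMap:
    """A per-voxel scalar field (ALFF map, GM volume map, beta map...)."""

    grid: VolumeGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise GridMismatchError(
                f"map shape {values.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "values", values)

    def with_values(self, values: np.ndarray) -> "ScalarMap":
        return replace(self, values=values)


@dataclass(frozen=True)
class Bold4D:
    """One subject's BOLD series: ``data`` has shape (T, nx, ny, nz)."""

    grid: VolumeGrid
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4 or data.shape[1:] != self.grid.shape:
            raise GridMismatchError(
                f"BOLD shape {data.shape} incompatible with grid {self.grid.shape}"
            )
        if data.shape[0] < MIN_TIMEPOINTS:
            raise ParameterError(
                f"BOLD series too short: {data.shape[0]} < {MIN_TIMEPOINTS} timepoints"
            )
        if self.tr_seconds <= 0:
            raise ParameterError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        if not np.isfinite(data).all():
            raise ValidationError("BOLD data contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds

    def timeseries(self, mask: np.ndarray) -> np.ndarray:
        """(T, V) matrix of the series at masked voxels."""
        return self.data[:, mask]

    def with_data(self, data: np.ndarray) -> "Bold4D":
        return replace(self, data=data)


def extract_roi_mean(values: ScalarMap | Bold4D, mask: np.ndarray):
    """Unweighted mean over masked voxels.

    Returns a scalar for a :class:`ScalarMap` and a length-T series for a
    :class:`Bold4D`.  An empty mask is an error, never a silent zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.grid.shape:
        raise GridMismatchError("mask shape does not match grid")
    if not mask.any():
        raise ParameterError("extract_roi_mean: empty mask")
    if isinstance(values, Bold4D):
        return values.data[:, mask].mean(axis=1)
    return float(values.values[mask].mean())


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _grid_from_img(img, brain_mask: np.ndarray | None) -> VolumeGrid:
    shape = tuple(int(s) for s in img.shape[:3])
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    return VolumeGrid(shape=shape, affine=np.asarray(img.affine), brain_mask=brain_mask)


def load_grid(mask_path) -> VolumeGrid:
    """Build a VolumeGrid from a brain-mask NIfTI (nonzero voxels = in brain)."""
    img = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    return _grid_from_img(img, np.asarray(data) > 0)


def load_scalar(path, grid: VolumeGrid | None = None, name: str = "") -> ScalarMap:
    img = nib.load(str(path))
    g = _grid_from_img(img, grid.brain_mask if grid is not None else None)
    if grid is not None:
        grid.require_match(g, what=str(path))
        g = grid
    return ScalarMap(grid=g, values=np.asanyarray(img.dataobj).astype(float), name=name)


def load_bold(path, grid: VolumeGrid | None = None, tr_seconds: float | None = None) -> Bold4D:
    """Load a 4D BOLD NIfTI; TR from the header pixdim unless given."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValidationError(f"{path}: expected a 4D volume, got ndim={img.ndim}")
    g = _grid_from_img(img, grid.brain_mask if grid is not None else None)
    if grid is not None:
        grid.require_match(g, what=str(path))
        g = grid
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3])
        if tr_seconds <= 0:
            raise ValidationError(f"{path}: no repetition time in header; pass tr_seconds")
    data = np.asanyarray(img.dataobj).astype(float)
    return Bold4D(grid=g, data=np.moveaxis(data, -1, 0), tr_seconds=tr_seconds)


def save_scalar(m: ScalarMap, path, sidecar: dict | None = None) -> None:
    img = nib.Nifti1Image(m.values.astype(np.float64), m.grid.affine)
    nib.save(img, str(path))
    if sidecar is not None:
        Path(str(path)).with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )


def save_mask(mask: np.ndarray, grid: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine)
    nib.save(img, str(path))


def save_bold(b: Bold4D, path) -> None:
    data = np.moveaxis(b.data, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, b.grid.affine)
    img.header.set_zooms((*b.grid.voxel_sizes_mm, b.tr_seconds))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

def read_phenotype(path) -> pd.DataFrame:
    """Read and validate the phenotype table (TSV or CSV, header required).

    Required columns: subject_id, center, sex, age.  Optional: tcv (total
    cranial volume, mm^3) and gmv (whole gray-matter volume, mm^3).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype {path}: missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"phenotype {path}: duplicate subject ids {dupes}")
    if df[list(REQUIRED_PHENOTYPE_COLUMNS)].isna().any().any():
        raise ValidationError(f"phenotype {path}: missing values in required columns")
    return df.reset_index(drop=True)
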