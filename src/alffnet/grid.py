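"""Volume geometry: grids, seed ROIs and sphere masks.

All volumes in a study live on a single :class:`VolumeGrid` — a 3-D raster
with a NIfTI-style affine mapping 0-based voxel indices to world (MNI) mm
coordinates in RAS orientation, plus a boolean brain mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import GridMismatchError, ParameterError, ROIOutsideBrainError

__all__ = [
    "VolumeGrid",
    "SeedROI",
    "ROISet",
    "sphere_roi_mask",
    "load_roi_sets",
    "default_roi_sets",
]

AFFINE_ATOL_MM = 1e-4  # tolerance when deciding two grids agree


@dataclass(frozen=True)
class VolumeGrid:
    """3-D raster geometry shared by every map in a study.

    Parameters
    ----------
    shape
        Voxels per axis.
    affine
        4x4 voxel-index -> mm matrix (NIfTI convention, RAS mm).
    brain_mask
        Boolean field on ``shape``; analyses are restricted to it.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ParameterError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ParameterError("affine is not invertible")
        object.__setattr__(self, "affine", aff)
        mask = np.asarray(self.brain_mask, dtype=bool)
        if mask.shape != shape:
            raise GridMismatchError(
                f"brain_mask shape {mask.shape} != grid shape {shape}"
            )
        if not mask.any():
            raise ParameterError("brain_mask has no true voxel")
        object.__setattr__(self, "brain_mask", mask)

    # -- coordinate transforms -------------------------------------------
    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_brain_voxels(self) -> int:
        return int(self.brain_mask.sum())

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) world mm coordinates to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def matches(self, other: "VolumeGrid", atol: float = AFFINE_ATOL_MM) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "VolumeGrid", what: str = "volume") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what}: shape/affine disagree "
                f"({self.shape} vs {other.shape})"
            )


@dataclass(frozen=True)
class SeedROI:
    """A spherical seed region defined in world (MNI) mm coordinates."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ParameterError(f"ROI {self.name}: radius must be > 0")
        object.__setattr__(
            self, "center_mm", tuple(float(c) for c in self.center_mm)
        )


@dataclass(frozen=True)
class ROISet:
    """A named set of exactly three seed ROIs (DMN, TPN or SN)."""

    label: str
    seeds: tuple[SeedROI, SeedROI, SeedROI]

    def __post_init__(self) -> None:
        if len(self.seeds) != 3:
            raise ParameterError(
                f"ROI set {self.label}: expected 3 seeds, got {len(self.seeds)}"
            )
        names = [s.name for s in self.seeds]
        if len(set(names)) != 3:
            raise ParameterError(f"ROI set {self.label}: duplicate seed names {names}")
        object.__setattr__(self, "seeds", tuple(self.seeds))


def sphere_roi_mask(roi: SeedROI, grid: VolumeGrid) -> np.ndarray:
    """Boolean mask of voxels whose center lies within the ROI sphere.

    A voxel belongs to the sphere when the Euclidean mm distance from its
    center to ``roi.center_mm`` is <= ``roi.radius_mm`` (no partial-volume
    weighting).  The result is intersected with the grid's brain mask.

    Raises
    ------
    ROIOutsideBrainError
        If no voxel survives the brain-mask intersection.
    """
    center_vox = grid.mm_to_voxel(np.asarray(roi.center_mm))
    # bounding box: radius in voxels along each axis, +1 voxel of slack
    half = roi.radius_mm / grid.voxel_sizes_mm + 1.0
    lo = np.maximum(np.floor(center_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + half).astype(int) + 1, grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    if np.any(lo >= hi):
        raise ROIOutsideBrainError(
            f"ROI {roi.name!r} at {roi.center_mm} lies outside the grid"
        )
    ii, jj, kk = np.meshgrid(
        *(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij"
    )
    box = np.stack([ii, jj, kk], axis=-1)
    dist = np.linalg.norm(grid.voxel_to_mm(box) - np.asarray(roi.center_mm), axis=-1)
    mask[ii, jj, kk] = dist <= roi.radius_mm + 1e-9
    mask &= grid.brain_mask
    if not mask.any():
        raise ROIOutsideBrainError(
            f"ROI {roi.name!r} at {roi.center_mm} (r={roi.radius_mm} mm) "
            "contains no in-brain voxel"
        )
    return mask


# ---------------------------------------------------------------------------
# ROI specification files
# ---------------------------------------------------------------------------

def _sets_from_entries(entries: Iterable[dict]) -> list[ROISet]:
    by_set: dict[str, list[SeedROI]] = {}
    for e in entries:
        roi = SeedROI(
            name=str(e["name"]),
            center_mm=(float(e["x"]), float(e["y"]), float(e["z"])),
            radius_mm=float(e.get("radius", 6.0)),
        )
        by_set.setdefault(str(e["set"]), []).append(roi)
    sets = [ROISet(label, tuple(seeds)) for label, seeds in by_set.items()]
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ParameterError(f"duplicate ROI set labels: {labels}")
    return sets


def load_roi_sets(path) -> list[ROISet]:
    """Load seed ROI sets from a YAML/JSON list of {name, set, x, y, z, radius}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ParameterError(f"ROI spec {path} must be a list of mappings")
    return _sets_from_entries(entries)


def default_roi_sets() -> list[ROISet]:
    """The nine default seed ROIs (three sets of three 6-mm spheres in MNI mm)."""
    from importlib.resources import files

    path = files("alffnet.data").joinpath("default_rois.yaml")
    entries = yaml.safe_load(path.read_text())
    return _sets_from_entries(entries)


def all_seeds(roi_sets: Sequence[ROISet]) -> list[tuple[str, SeedROI]]:
    """Flatten ROI sets to (set_label, seed) pairs in declaration order."""
    return [(s.label, roi) for s in roi_sets for roi in s.seeds]
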