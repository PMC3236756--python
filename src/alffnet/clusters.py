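"""Cluster tables: connected components of thresholded maps with peak reporting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import ThresholdedMap

__all__ = ["ClusterTableRow", "cluster_table", "cluster_table_frame"]

# 26-connectivity: all voxels sharing a face, edge or corner
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ClusterTableRow:
    label: str
    peak_mm: tuple[float, float, float]
    peak_t: float
    voxel_count: int


def _components(mask: np.ndarray, t: np.ndarray, grid, sign: str, min_voxels: int):
    labels, n = ndimage.label(mask, structure=_STRUCTURE)
    rows = []
    for comp in range(1, n + 1):
        idx = np.argwhere(labels == comp)
        if len(idx) < min_voxels:
            continue
        tv = t[tuple(idx.T)]
        peak = idx[np.argmax(np.abs(tv))]
        peak_mm = tuple(float(c) for c in grid.voxel_to_mm(peak))
        rows.append(
            ClusterTableRow(
                label=f"{sign}",
                peak_mm=peak_mm,
                peak_t=float(t[tuple(peak)]),
                voxel_count=len(idx),
            )
        )
    return rows


def cluster_table(thr: ThresholdedMap, min_voxels: int = 1) -> list[ClusterTableRow]:
    """Connected components (26-connectivity) of the pos and neg masks.

    Components smaller than ``min_voxels`` are dropped.  Each row reports the
    peak |t| voxel's world mm coordinates, the signed peak t and the voxel
    count; rows are sorted by voxel count descending (peak |t| breaks ties).
    """
    grid = thr.grid
    t = thr.source.t_values
    rows = _components(thr.pos_mask, t, grid, "pos", min_voxels)
    rows += _components(thr.neg_mask, t, grid, "neg", min_voxels)
    rows.sort(key=lambda r: (-r.voxel_count, -abs(r.peak_t)))
    # number the rows after sorting so labels are stable
    return [
        ClusterTableRow(f"{r.label}_{i + 1}", r.peak_mm, r.peak_t, r.voxel_count)
        for i, r in enumerate(rows)
    ]


def cluster_table_frame(rows: list[ClusterTableRow]) -> pd.DataFrame:
    """Cluster rows as a DataFrame with columns label, x, y, z, peak_t, voxels."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "x": r.peak_mm[0],
                "y": r.peak_mm[1],
                "z": r.peak_mm[2],
                "peak_t": r.peak_t,
                "voxels": r.voxel_count,
            }
            for r in rows
        ],
        columns=["label", "x", "y", "z", "peak_t", "voxels"],
    )
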