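"""Map-space analytics: spatial correlation, hierarchical clustering of
network maps, conjunction analysis and the two-system dichotomy statistics.

The nine seed-network t-maps are compared by Pearson correlation over the
brain mask, converted to a dissimilarity (default d = 1 - r, so the standard
cut height 0.4 corresponds to spatial r = 0.6), and agglomerated
hierarchically (average linkage by default).  Conjunction analysis keeps
voxels that are sign-consistently significant in at least k of n maps
(k = 2 of 3 within a seed set; k = 8 of 9 across sets after sign-flipping
the sensory set), which carves the brain into the anti-correlated high-level
(DMN+TPN) and low-level (sensory) systems.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateInputError, GridMismatchError, ParameterError
from .glm import (
    CohortMatrix,
    StatMap,
    ThresholdedMap,
    fwe_threshold,
    group_onesample_t,
)
from .grid import VolumeGrid
from .images import ScalarMap

__all__ = [
    "spatial_correlation",
    "dissimilarity",
    "MapDistanceMatrix",
    "map_distance_matrix",
    "Dendrogram",
    "hierarchical_cluster",
    "ConjunctionMap",
    "conjunction_intra_set",
    "conjunction_inter_set",
    "ts_icn_dichotomy",
    "DichotomyResult",
    "dichotomy_statistics",
]

DISSIMILARITY_FORMULAS = ("one_minus_r", "sqrt_two_one_minus_r", "half_one_minus_r")
DEFAULT_CUT_HEIGHT = 0.4


def spatial_correlation(a: StatMap, b: StatMap, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two t-fields over masked voxels."""
    a.grid.require_match(b.grid, what="spatial_correlation maps")
    mask = a.grid.brain_mask if mask is None else np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ParameterError("spatial_correlation: mask must contain >= 3 voxels")
    x, y = a.t_values[mask], b.t_values[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("spatial_correlation: map constant on mask")
    return float(np.corrcoef(x, y)[0, 1])


def dissimilarity(r: float, formula: str = "one_minus_r") -> float:
    """Convert a spatial correlation to a dissimilarity distance.

    Variants: d = 1 - r (default), d = sqrt(2 (1 - r)), d = (1 - r) / 2.
    All satisfy d(1) = 0 and are strictly decreasing in r.
    """
    if abs(r) > 1 + 1e-12:
        raise ParameterError(f"correlation out of range: {r}")
    r = float(np.clip(r, -1.0, 1.0))
    if formula == "one_minus_r":
        return 1.0 - r
    if formula == "sqrt_two_one_minus_r":
        return float(np.sqrt(2.0 * (1.0 - r)))
    if formula == "half_one_minus_r":
        return (1.0 - r) / 2.0
    raise ParameterError(
        f"unknown dissimilarity formula {formula!r}; choose from {DISSIMILARITY_FORMULAS}"
    )


@dataclass(frozen=True)
class MapDistanceMatrix:
    """Pairwise spatial correlations and dissimilarities of network maps."""

    labels: tuple[str, ...]
    r: np.ndarray
    d: np.ndarray
    formula: str = "one_minus_r"


def map_distance_matrix(
    maps: Sequence[StatMap],
    labels: Sequence[str] | None = None,
    mask: np.ndarray | None = None,
    formula: str = "one_minus_r",
) -> MapDistanceMatrix:
    """All-pairs spatial correlation and dissimilarity of a list of StatMaps."""
    n = len(maps)
    labels = tuple(labels) if labels is not None else tuple(m.seed_name for m in maps)
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = spatial_correlation(maps[i], maps[j], mask)
    d = np.vectorize(lambda v: dissimilarity(v, formula))(r)
    np.fill_diagonal(d, 0.0)
    return MapDistanceMatrix(labels=labels, r=r, d=d, formula=formula)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over network maps.

    ``merges`` is the scipy linkage matrix: each row merges two clusters at a
    height; ``cut(h)`` returns the partition obtained by removing merges
    above h, as a label -> cluster-id mapping.
    """

    labels: tuple[str, ...]
    merges: np.ndarray
    method: str

    def cut(self, height: float) -> dict[str, int]:
        assignments = fcluster(self.merges, t=height, criterion="distance")
        return {lab: int(c) for lab, c in zip(self.labels, assignments)}

    def n_clusters(self, height: float) -> int:
        return len(set(self.cut(height).values()))


def hierarchical_cluster(
    dm: MapDistanceMatrix,
    method: str = "average",
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> tuple[Dendrogram, dict[str, int]]:
    """Agglomerate maps by minimal inter-cluster dissimilarity.

    Default linkage is average (UPGMA); 'single' and 'complete' are also
    supported.  Returns the dendrogram and the partition at ``cut_height``.
    """
    if method not in ("average", "single", "complete"):
        raise ParameterError(f"unsupported linkage {method!r}")
    d = np.asarray(dm.d, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ParameterError("distance matrix must be square symmetric")
    Z = scipy_linkage(squareform(d, checks=False), method=method)
    dend = Dendrogram(labels=dm.labels, merges=Z, method=method)
    return dend, dend.cut(cut_height)


# ---------------------------------------------------------------------------
# Conjunction analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConjunctionMap:
    """k-of-n sign-consistent conjunction of thresholded maps.

    ``mean_t`` is the arithmetic mean of the (unthresholded) t-fields,
    reported only inside the union of the two masks (zero elsewhere).
    """

    grid: VolumeGrid
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    mean_t: np.ndarray
    k: int
    n: int
    flip_set: str | None = None


def _conjoin(thr_maps: Sequence[ThresholdedMap], k: int, flip: Sequence[bool],
             flip_set: str | None) -> ConjunctionMap:
    grid = thr_maps[0].grid
    pos_count = np.zeros(grid.shape, dtype=int)
    neg_count = np.zeros(grid.shape, dtype=int)
    t_sum = np.zeros(grid.shape)
    for m, fl in zip(thr_maps, flip):
        grid.require_match(m.grid, what="conjunction map")
        pos, neg = (m.neg_mask, m.pos_mask) if fl else (m.pos_mask, m.neg_mask)
        sgn = -1.0 if fl else 1.0
        pos_count += pos
        neg_count += neg
        t_sum += sgn * m.source.t_values
    n = len(thr_maps)
    pos_mask = pos_count >= k
    neg_mask = neg_count >= k
    mean_t = np.where(pos_mask | neg_mask, t_sum / n, 0.0)
    return ConjunctionMap(
        grid=grid, pos_mask=pos_mask, neg_mask=neg_mask, mean_t=mean_t,
        k=k, n=n, flip_set=flip_set,
    )


def conjunction_intra_set(thr_maps: Sequence[ThresholdedMap], k: int = 2) -> ConjunctionMap:
    """Voxels sign-consistently significant in >= k of the set's maps.

    Positive and negative significances are counted separately: a voxel
    positive in one map and negative in another never combines.
    """
    if not 1 <= k <= len(thr_maps):
        raise ParameterError(f"k={k} out of range for {len(thr_maps)} maps")
    return _conjoin(thr_maps, k, [False] * len(thr_maps), None)


def conjunction_inter_set(
    thr_by_set: Mapping[str, Sequence[ThresholdedMap]],
    flip_set: str = "SN",
    k: int = 8,
) -> ConjunctionMap:
    """k-of-n conjunction across seed sets, sign-flipping ``flip_set`` first.

    With the default FCN inputs the resulting pos_mask is the high-level
    (DMN+TPN) system and neg_mask the low-level (sensory) system.
    """
    if flip_set not in thr_by_set:
        raise ParameterError(f"flip_set {flip_set!r} not among sets {list(thr_by_set)}")
    maps: list[ThresholdedMap] = []
    flips: list[bool] = []
    for label, ms in thr_by_set.items():
        maps.extend(ms)
        flips.extend([label == flip_set] * len(ms))
    if not 1 <= k <= len(maps):
        raise ParameterError(f"k={k} out of range for {len(maps)} maps")
    return _conjoin(maps, k, flips, flip_set)


def ts_icn_dichotomy(
    subject_maps_by_set: Mapping[str, Sequence[Sequence[ScalarMap]]],
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    dmn_label: str = "DMN",
    tpn_label: str = "TPN",
) -> tuple[StatMap, ThresholdedMap]:
    """Task-positive vs default-mode dichotomy from subject-level ICN z-maps.

    ``subject_maps_by_set[label][seed][subject]`` are per-subject Fisher-z
    maps.  Per subject the DMN maps are multiplied by -1 and averaged with
    the TPN maps; the combined map is tested with a covariate-adjusted
    one-sample t and FWE-thresholded.  pos_mask marks the TPN-positive /
    DMN-negative system.
    """
    dmn = subject_maps_by_set[dmn_label]
    tpn = subject_maps_by_set[tpn_label]
    n_subj = len(dmn[0])
    grid = dmn[0][0].grid
    combined: list[ScalarMap] = []
    for s in range(n_subj):
        # sum each side separately so identical inputs cancel exactly
        acc_dmn = np.zeros(grid.shape)
        for seed_maps in dmn:
            acc_dmn += seed_maps[s].values
        acc_tpn = np.zeros(grid.shape)
        for seed_maps in tpn:
            acc_tpn += seed_maps[s].values
        cnt = len(dmn) + len(tpn)
        combined.append(
            ScalarMap(grid=grid, values=(acc_tpn - acc_dmn) / cnt, name="ts_dichotomy")
        )
    stat = group_onesample_t(
        combined, covariates=covariates, seed_name="TPN-DMN", estimator="TS-ICN"
    )
    return stat, fwe_threshold(stat, alpha)


# ---------------------------------------------------------------------------
# Dichotomy statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DichotomyResult:
    """Across-subject statistics of the two-system dichotomy.

    ``high_means`` / ``low_means`` are the per-subject mean (standardized)
    ALFF inside each system; ``r`` their Pearson correlation, ``t_twosample``
    the Welch two-sample t comparing their levels.
    """

    high_means: np.ndarray
    low_means: np.ndarray
    r: float
    r_pvalue: float
    t_twosample: float
    t_pvalue: float
    high_mean_sd: tuple[float, float]
    low_mean_sd: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "r_pvalue": self.r_pvalue,
            "t_twosample": self.t_twosample,
            "t_pvalue": self.t_pvalue,
            "high_mean": self.high_mean_sd[0],
            "high_sd": self.high_mean_sd[1],
            "low_mean": self.low_mean_sd[0],
            "low_sd": self.low_mean_sd[1],
            "n_subjects": int(len(self.high_means)),
        }


def dichotomy_statistics(
    alff_cohort: CohortMatrix, high_mask: np.ndarray, low_mask: np.ndarray
) -> DichotomyResult:
    """Correlate per-subject mean ALFF of the two systems across subjects."""
    grid = alff_cohort.grid
    high = np.asarray(high_mask, dtype=bool)
    low = np.asarray(low_mask, dtype=bool)
    if high.shape != grid.shape or low.shape != grid.shape:
        raise GridMismatchError("dichotomy masks must match the grid shape")
    if (high & low).any():
        raise ParameterError("dichotomy masks must be disjoint")
    hi_in, lo_in = high[grid.brain_mask], low[grid.brain_mask]
    if not hi_in.any() or not lo_in.any():
        raise ParameterError("dichotomy masks must both be non-empty in the brain")
    hm = alff_cohort.data[:, hi_in].mean(axis=1)
    lm = alff_cohort.data[:, lo_in].mean(axis=1)
    r, r_p = stats.pearsonr(hm, lm)
    t, t_p = stats.ttest_ind(hm, lm, equal_var=False)
    return DichotomyResult(
        high_means=hm,
        low_means=lm,
        r=float(r),
        r_pvalue=float(r_p),
        t_twosample=float(t),
        t_pvalue=float(t_p),
        high_mean_sd=(float(hm.mean()), float(hm.std(ddof=1))),
        low_mean_sd=(float(lm.mean()), float(lm.std(ddof=1))),
    )
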