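"""Spatial correlation, clustering, conjunctions and dichotomy statistics."""

import numpy as np
import pytest

from alffnet.errors import DegenerateInputError, ParameterError
from alffnet.glm import CohortMatrix, StatMap, ThresholdedMap
from alffnet.topology import (
    MapDistanceMatrix,
    conjunction_inter_set,
    conjunction_intra_set,
    dichotomy_statistics,
    dissimilarity,
    hierarchical_cluster,
    spatial_correlation,
    ts_icn_dichotomy,
)
from alffnet.images import ScalarMap

from conftest import centered_grid


def statmap(t, grid, name=""):
    return StatMap(grid=grid, t_values=t, df=20, seed_name=name)


def thr_from_signs(pos_voxels, neg_voxels, grid, t_crit=2.0):
    """ThresholdedMap from explicit voxel index lists on a flat grid."""
    t = np.zeros(grid.shape)
    pos = np.zeros(grid.shape, bool)
    neg = np.zeros(grid.shape, bool)
    for v in pos_voxels:
        pos[v, 0, 0] = True
        t[v, 0, 0] = 3.0
    for v in neg_voxels:
        neg[v, 0, 0] = True
        t[v, 0, 0] = -3.0
    return ThresholdedMap(
        source=statmap(t, grid), alpha_fwe=0.05, t_crit=t_crit,
        pos_mask=pos, neg_mask=neg,
    )


# ---------------------------------------------------------------------------
# spatial correlation & dissimilarity
# ---------------------------------------------------------------------------

def test_spatial_correlation_identity_and_negation(rng):
    grid = centered_grid(shape=(6, 6, 6))
    t = rng.standard_normal(grid.shape)
    a = statmap(t, grid)
    assert spatial_correlation(a, a) == pytest.approx(1.0)
    assert spatial_correlation(a, statmap(-t, grid)) == pytest.approx(-1.0)


def test_spatial_correlation_hand_value():
    grid = centered_grid(shape=(5, 1, 1))
    a = statmap(np.array([1, 2, 3, 4, 5], float).reshape(5, 1, 1), grid)
    b = statmap(np.array([2, 1, 4, 3, 5], float).reshape(5, 1, 1), grid)
    assert spatial_correlation(a, b) == pytest.approx(0.8)


def test_spatial_correlation_constant_map_rejected():
    grid = centered_grid(shape=(5, 1, 1))
    a = statmap(np.ones((5, 1, 1)), grid)
    b = statmap(np.arange(5.0).reshape(5, 1, 1), grid)
    with pytest.raises(DegenerateInputError):
        spatial_correlation(a, b)


@pytest.mark.parametrize(
    "r,expected",
    [(1.0, 0.0), (-1.0, 2.0), (0.6, 0.4)],
)
def test_dissimilarity_default_formula(r, expected):
    assert dissimilarity(r) == pytest.approx(expected)


def test_dissimilarity_variants_monotone_decreasing():
    rs = np.linspace(-1, 1, 41)
    for formula in ("one_minus_r", "sqrt_two_one_minus_r", "half_one_minus_r"):
        d = [dissimilarity(r, formula) for r in rs]
        assert all(a > b for a, b in zip(d, d[1:]))
        assert d[-1] == pytest.approx(0.0)  # d(1) = 0


def test_dissimilarity_out_of_range_rejected():
    with pytest.raises(ParameterError):
        dissimilarity(1.5)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def _dm(d, labels=None):
    d = np.asarray(d, float)
    labels = labels or tuple(f"m{i}" for i in range(d.shape[0]))
    return MapDistanceMatrix(labels=tuple(labels), r=1 - d, d=d)


def test_identical_maps_merge_at_zero():
    d = np.zeros((9, 9))
    dend, part = hierarchical_cluster(_dm(d), cut_height=0.4)
    assert len(set(part.values())) == 1
    assert np.allclose(dend.merges[:, 2], 0.0)


def test_three_block_structure_recovered_at_cut():
    labels = [f"m{i}" for i in range(9)]
    d = np.full((9, 9), 0.9)
    for blk in (slice(0, 3), slice(3, 6), slice(6, 9)):
        d[blk, blk] = 0.1
    np.fill_diagonal(d, 0.0)
    _, part = hierarchical_cluster(_dm(d, labels), cut_height=0.4)
    groups = {}
    for lab, c in part.items():
        groups.setdefault(c, set()).add(lab)
    assert sorted(map(sorted, groups.values())) == [
        ["m0", "m1", "m2"], ["m3", "m4", "m5"], ["m6", "m7", "m8"]
    ]


def test_fcn_like_structure_two_clusters():
    """DMN-TPN between-block d=0.3 merges them; SN stays apart at cut 0.4."""
    labels = ["PCC", "DMPFC", "AG", "DLPFC", "IPL", "FEF", "SC", "VC", "AC"]
    d = np.full((9, 9), 0.9)
    d[0:6, 0:6] = 0.3
    for blk in (slice(0, 3), slice(3, 6), slice(6, 9)):
        d[blk, blk] = 0.1
    np.fill_diagonal(d, 0.0)
    _, part = hierarchical_cluster(_dm(d, labels), cut_height=0.4)
    assert len(set(part.values())) == 2
    assert len({part[l] for l in labels[:6]}) == 1
    assert len({part[l] for l in labels[6:]}) == 1
    assert part["PCC"] != part["SC"]


def test_cut_height_monotone_cluster_count(rng):
    d = np.abs(rng.standard_normal((9, 9)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    dend, _ = hierarchical_cluster(_dm(d))
    counts = [dend.n_clusters(h) for h in np.linspace(0, d.max() * 2, 25)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert dend.n_clusters(0.0) == 9
    assert dend.n_clusters(1e9) == 1


# ---------------------------------------------------------------------------
# conjunctions
# ---------------------------------------------------------------------------

def test_intra_conjunction_enumerated_counting_rule():
    grid = centered_grid(shape=(5, 1, 1))
    # voxel -> which of the 3 maps mark it positive
    m1 = thr_from_signs([0, 1, 3], [], grid)
    m2 = thr_from_signs([0, 2, 3], [], grid)
    m3 = thr_from_signs([2, 3], [], grid)
    cj = conjunction_intra_set([m1, m2, m3], k=2)
    assert list(np.flatnonzero(cj.pos_mask[:, 0, 0])) == [0, 2, 3]
    assert not cj.neg_mask.any()


def test_conjunction_signs_never_mix():
    grid = centered_grid(shape=(1, 1, 1))
    pos = thr_from_signs([0], [], grid)
    neg = thr_from_signs([], [0], grid)
    none = thr_from_signs([], [], grid)
    cj = conjunction_intra_set([pos, neg, none], k=2)
    assert not cj.pos_mask.any() and not cj.neg_mask.any()


def test_conjunction_k1_union_k3_intersection(rng):
    grid = centered_grid(shape=(30, 1, 1))
    maps = []
    for _ in range(3):
        pos = list(np.flatnonzero(rng.random(30) < 0.4))
        neg = list(np.flatnonzero((rng.random(30) < 0.4)))
        neg = [v for v in neg if v not in pos]
        maps.append(thr_from_signs(pos, neg, grid))
    union = conjunction_intra_set(maps, k=1)
    inter = conjunction_intra_set(maps, k=3)
    assert np.array_equal(union.pos_mask, maps[0].pos_mask | maps[1].pos_mask | maps[2].pos_mask)
    assert np.array_equal(union.neg_mask, maps[0].neg_mask | maps[1].neg_mask | maps[2].neg_mask)
    assert np.array_equal(inter.pos_mask, maps[0].pos_mask & maps[1].pos_mask & maps[2].pos_mask)
    assert np.array_equal(inter.neg_mask, maps[0].neg_mask & maps[1].neg_mask & maps[2].neg_mask)


def test_inter_set_flip_logic_nine_of_nine():
    grid = centered_grid(shape=(3, 1, 1))
    # voxel 0: positive in all DMN/TPN maps, negative in all SN maps -> pos after flip
    # voxel 1: sign-consistent in only 7 of 9 -> excluded at k=8
    dmn = [thr_from_signs([0, 1], [], grid) for _ in range(3)]
    tpn = [thr_from_signs([0, 1], [], grid) for _ in range(3)]
    sn = [thr_from_signs([], [0], grid) for _ in range(2)]
    sn.append(thr_from_signs([], [], grid))  # voxel 1 misses 2 SN maps, voxel 0 one
    cj = conjunction_inter_set({"DMN": dmn, "TPN": tpn, "SN": sn}, flip_set="SN", k=8)
    assert cj.pos_mask[0, 0, 0]
    assert not cj.pos_mask[1, 0, 0]  # 6 of 9 only
    assert not cj.neg_mask.any()
    assert cj.flip_set == "SN"


def test_inter_set_flip_equivariance(rng):
    """Relabeling the flipped set while negating its maps leaves masks fixed."""
    grid = centered_grid(shape=(20, 1, 1))

    def rand_thr(negate=False):
        t = rng.standard_normal((20, 1, 1)) * 4
        if negate:
            t = -t
        sm = statmap(t, grid)
        return ThresholdedMap(
            source=sm, alpha_fwe=0.05, t_crit=2.0,
            pos_mask=t >= 2.0, neg_mask=t <= -2.0,
        )

    rng_state = rng.bit_generator.state
    sets_a = {"DMN": [rand_thr() for _ in range(3)],
              "TPN": [rand_thr() for _ in range(3)],
              "SN": [rand_thr() for _ in range(3)]}
    rng.bit_generator.state = rng_state
    sets_b = {"DMN": [rand_thr() for _ in range(3)],
              "TPN": [rand_thr() for _ in range(3)],
              "SN": [rand_thr(negate=True) for _ in range(3)]}
    cj_a = conjunction_inter_set(sets_a, flip_set="SN", k=8)
    # negating SN's t-fields and *not* flipping is the same counting problem
    cj_b = conjunction_inter_set({**sets_b, "SN": sets_a["SN"]}, flip_set="SN", k=8)
    assert np.array_equal(cj_a.pos_mask, cj_b.pos_mask)
    assert np.array_equal(cj_a.neg_mask, cj_b.neg_mask)


# ---------------------------------------------------------------------------
# TS-ICN dichotomy
# ---------------------------------------------------------------------------

def _subject_maps(values_list, grid):
    return [ScalarMap(grid=grid, values=v) for v in values_list]


def test_ts_dichotomy_identical_maps_cancel(rng):
    grid = centered_grid(shape=(4, 1, 1))
    n = 8
    per_subject = [rng.standard_normal(grid.shape) for _ in range(n)]
    sets = {
        "DMN": [_subject_maps(per_subject, grid) for _ in range(3)],
        "TPN": [_subject_maps(per_subject, grid) for _ in range(3)],
    }
    stat, thr = ts_icn_dichotomy(sets)
    assert np.allclose(stat.t_values, 0.0)


def test_ts_dichotomy_opposed_maps_yield_positive_system(rng):
    grid = centered_grid(shape=(4, 1, 1))
    n = 12
    m = np.zeros(grid.shape)
    m[0, 0, 0] = 1.0
    dmn_maps, tpn_maps = [], []
    for _ in range(n):
        jitter = 0.01 * rng.standard_normal(grid.shape)
        dmn_maps.append(-m + jitter)
        tpn_maps.append(m + jitter)
    sets = {
        "DMN": [_subject_maps(dmn_maps, grid) for _ in range(3)],
        "TPN": [_subject_maps(tpn_maps, grid) for _ in range(3)],
    }
    stat, thr = ts_icn_dichotomy(sets)
    assert thr.pos_mask[0, 0, 0]


# ---------------------------------------------------------------------------
# dichotomy statistics
# ---------------------------------------------------------------------------

def _cohort(data, grid):
    return CohortMatrix(grid=grid, data=data, subject_ids=[f"s{i}" for i in range(len(data))])


def test_dichotomy_perfect_anticorrelation():
    grid = centered_grid(shape=(2, 1, 1))
    n = 20
    h = np.linspace(0.8, 1.2, n)
    data = np.column_stack([h, -h + 2.5])
    high = np.zeros(grid.shape, bool); high[0, 0, 0] = True
    low = np.zeros(grid.shape, bool); low[1, 0, 0] = True
    res = dichotomy_statistics(_cohort(data, grid), high, low)
    assert res.r == pytest.approx(-1.0)


def test_dichotomy_independent_vectors_small_r(rng):
    grid = centered_grid(shape=(2, 1, 1))
    n = 300
    data = rng.standard_normal((n, 2))
    high = np.zeros(grid.shape, bool); high[0, 0, 0] = True
    low = np.zeros(grid.shape, bool); low[1, 0, 0] = True
    res = dichotomy_statistics(_cohort(data, grid), high, low)
    assert abs(res.r) < 0.2  # null |r| at n=300 exceeds 0.2 with p < 1e-3


def test_dichotomy_masks_must_be_disjoint_nonempty():
    grid = centered_grid(shape=(2, 1, 1))
    data = np.random.default_rng(0).standard_normal((10, 2))
    both = np.ones(grid.shape, bool)
    with pytest.raises(ParameterError):
        dichotomy_statistics(_cohort(data, grid), both, both)
    empty = np.zeros(grid.shape, bool)
    high = np.zeros(grid.shape, bool); high[0, 0, 0] = True
    with pytest.raises(ParameterError):
        dichotomy_statistics(_cohort(data, grid), high, empty)
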