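"""Estimator engines: ICN maps, one-sample t, across-subject covariance GLM,
FWE thresholding and cluster tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alffnet.clusters import cluster_table
from alffnet.errors import CollinearDesignError, DegenerateInputError, ParameterError
from alffnet.glm import (
    CohortMatrix,
    StatMap,
    crosssubject_covariance_map,
    encode_covariates,
    fwe_threshold,
    group_onesample_t,
    subject_icn_map,
    vbm_scn_map,
)
from alffnet.images import Bold4D, ScalarMap

from conftest import centered_grid


def flat_cohort(data, grid=None):
    n, V = data.shape
    grid = grid or centered_grid(shape=(V, 1, 1))
    return CohortMatrix(grid=grid, data=data, subject_ids=[f"s{i}" for i in range(n)])


def residualize_then_correlate_t(Y, seed, Z):
    """Independent oracle: project out [1 | Z], then the correlation-t formula
    with df = n - 2 - c."""
    n = len(seed)
    c = Z.shape[1]
    X0 = np.column_stack([np.ones(n), Z])
    P = X0 @ np.linalg.pinv(X0)
    Yr = Y - P @ Y
    sr = seed - P @ seed
    r = (sr @ Yr) / (np.linalg.norm(sr) * np.linalg.norm(Yr, axis=0))
    df = n - 2 - c
    return r * np.sqrt(df) / np.sqrt(1 - r**2), df


# ---------------------------------------------------------------------------
# subject_icn_map
# ---------------------------------------------------------------------------

def _bold_matrix(M, tr=2.0):
    T, V = M.shape
    grid = centered_grid(shape=(V, 1, 1))
    return Bold4D(grid=grid, data=M.reshape(T, V, 1, 1), tr_seconds=tr), grid


def test_icn_self_correlation_is_clipped_atanh(rng):
    s = rng.standard_normal(100)
    M = np.column_stack([s, s, rng.standard_normal(100)])
    bold, grid = _bold_matrix(M)
    seed_mask = np.zeros(grid.shape, bool)
    seed_mask[0, 0, 0] = True
    z = subject_icn_map(bold, seed_mask)
    assert z.values[1, 0, 0] == pytest.approx(np.arctanh(1 - 1e-7))


def test_icn_orthogonal_series_zero_z():
    t = np.arange(100)
    M = np.column_stack([np.sin(2 * np.pi * 5 * t / 100), np.cos(2 * np.pi * 5 * t / 100)])
    bold, grid = _bold_matrix(M)
    seed_mask = np.zeros(grid.shape, bool)
    seed_mask[0, 0, 0] = True
    z = subject_icn_map(bold, seed_mask)
    assert abs(z.values[1, 0, 0]) < 1e-10


def test_icn_nuisance_column_regressed_to_zero(rng):
    g = rng.standard_normal(120)  # "global signal"
    seed = rng.standard_normal(120)
    M = np.column_stack([seed, g + 1e-3 * rng.standard_normal(120), g])
    bold, grid = _bold_matrix(M)
    seed_mask = np.zeros(grid.shape, bool)
    seed_mask[0, 0, 0] = True
    z = subject_icn_map(bold, seed_mask, nuisance=g[:, None], nuisance_names=["global"])
    # voxel 2 equals the nuisance column exactly -> residual constant -> z = 0
    assert abs(z.values[2, 0, 0]) < 1e-8


def test_icn_rank_deficient_nuisance_names_columns(rng):
    M = rng.standard_normal((60, 3))
    bold, grid = _bold_matrix(M)
    seed_mask = np.zeros(grid.shape, bool)
    seed_mask[0, 0, 0] = True
    g = rng.standard_normal(60)
    with pytest.raises(CollinearDesignError, match="dup"):
        subject_icn_map(
            bold, seed_mask, nuisance=np.column_stack([g, g]),
            nuisance_names=["global", "dup"],
        )


# ---------------------------------------------------------------------------
# group_onesample_t
# ---------------------------------------------------------------------------

def test_onesample_matches_textbook_formula(rng):
    n, V = 30, 50
    data = rng.standard_normal((n, V))
    stat = group_onesample_t(flat_cohort(data))
    expected = data.mean(0) / (data.std(0, ddof=1) / np.sqrt(n))
    got = stat.t_values[stat.grid.brain_mask]
    assert np.allclose(got, expected, rtol=1e-10)
    assert stat.df == n - 1


def test_onesample_identical_maps_capped_not_nan():
    n, V = 10, 4
    data = np.tile(np.array([1.0, -2.0, 0.0, 3.0]), (n, 1))
    stat = group_onesample_t(flat_cohort(data))
    t = stat.t_values[stat.grid.brain_mask]
    assert np.isfinite(t).all()
    assert t[0] > 1e6 and t[1] < -1e6 and t[2] == 0.0
    assert stat.degenerate_mask[stat.grid.brain_mask].all()


def test_onesample_centered_covariate_absorbs_variance_not_mean(rng):
    """Mean-centering makes the intercept the covariate-adjusted group mean:
    a covariate that tracks a voxel's between-subject deviations leaves the
    intercept estimate at the group mean while shrinking its standard error."""
    n = 40
    v = rng.standard_normal(n) + 1.5
    data = v[:, None].copy()
    cov = (v + 0.1 * rng.standard_normal(n))[:, None]
    plain = group_onesample_t(flat_cohort(data))
    adj = group_onesample_t(flat_cohort(data), covariates=cov)
    assert adj.df == plain.df - 1
    # same tested effect (the group mean), higher precision
    t_plain = plain.t_values.ravel()[0]
    t_adj = adj.t_values.ravel()[0]
    assert np.sign(t_adj) == np.sign(t_plain)
    assert abs(t_adj) > abs(t_plain)


def test_onesample_insufficient_subjects_raises(rng):
    data = rng.standard_normal((3, 5))
    with pytest.raises(ParameterError, match="insufficient"):
        group_onesample_t(flat_cohort(data), covariates=rng.standard_normal((3, 2)))


# ---------------------------------------------------------------------------
# crosssubject_covariance_map / vbm_scn_map
# ---------------------------------------------------------------------------

def test_covariance_map_equals_residualize_oracle(rng):
    n, V, c = 50, 200, 3
    Y = rng.standard_normal((n, V))
    seed = rng.standard_normal(n)
    Z = rng.standard_normal((n, c))
    stat = crosssubject_covariance_map(flat_cohort(Y), seed, covariates=Z)
    t_oracle, df = residualize_then_correlate_t(Y, seed, Z)
    assert stat.df == df == n - 2 - c
    got = stat.t_values[stat.grid.brain_mask]
    assert np.max(np.abs(got - t_oracle)) < 1e-8


def test_covariance_map_no_covariate_closed_form(rng):
    n, V = 20, 100
    Y = rng.standard_normal((n, V))
    seed = rng.standard_normal(n)
    stat = crosssubject_covariance_map(flat_cohort(Y), seed)
    sc = seed - seed.mean()
    Yc = Y - Y.mean(0)
    r = (sc @ Yc) / (np.linalg.norm(sc) * np.linalg.norm(Yc, axis=0))
    expected = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    got = stat.t_values[stat.grid.brain_mask]
    assert np.max(np.abs(got - expected)) < 1e-8


def test_covariance_map_orthogonal_voxel_t_zero(rng):
    n = 24
    seed = np.sin(np.arange(n))
    v = rng.standard_normal(n)
    sc = seed - seed.mean()
    v = v - v.mean()
    v = v - (v @ sc) / (sc @ sc) * sc  # sample correlation exactly 0
    stat = crosssubject_covariance_map(flat_cohort(v[:, None]), seed)
    assert abs(stat.t_values.ravel()[0]) < 1e-10


def test_constant_seed_rejected(rng):
    with pytest.raises(DegenerateInputError):
        crosssubject_covariance_map(
            flat_cohort(rng.standard_normal((20, 5))), np.ones(20)
        )


def test_vbm_scn_delegates_to_same_engine(rng):
    n, V = 30, 40
    Y = rng.standard_normal((n, V))
    seed = rng.standard_normal(n)
    Z = rng.standard_normal((n, 2))
    a = vbm_scn_map(flat_cohort(Y), seed, covariates=Z)
    b = crosssubject_covariance_map(flat_cohort(Y), seed, covariates=Z)
    assert np.array_equal(a.t_values, b.t_values)
    assert a.estimator == "VBM-SCN"


def test_sign_symmetry(rng):
    n, V = 25, 30
    Y = rng.standard_normal((n, V))
    seed = rng.standard_normal(n)
    Z = rng.standard_normal((n, 2))
    t_pos = crosssubject_covariance_map(flat_cohort(Y), seed, covariates=Z).t_values
    t_neg = crosssubject_covariance_map(flat_cohort(Y), -seed, covariates=Z).t_values
    assert np.array_equal(t_pos, -t_neg)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_permutation_invariance(seed_int):
    rng = np.random.default_rng(seed_int)
    n, V = 20, 15
    Y = rng.standard_normal((n, V))
    seed = rng.standard_normal(n)
    Z = rng.standard_normal((n, 2))
    perm = rng.permutation(n)
    t0 = crosssubject_covariance_map(flat_cohort(Y), seed, covariates=Z).t_values
    t1 = crosssubject_covariance_map(
        flat_cohort(Y[perm]), seed[perm], covariates=Z[perm]
    ).t_values
    assert np.allclose(t0, t1, atol=1e-12)


def test_planted_structural_covariance_detected(rng):
    """A factor shared by seed and partner region crosses the FWE threshold."""
    n, V = 100, 50
    factor = rng.standard_normal(n)
    Y = rng.standard_normal((n, V))
    target = 0.7
    lam = target / np.sqrt(1 - target**2)  # gives corr ~0.7 with unit noise
    Y[:, 10] = lam * factor + rng.standard_normal(n)
    seed = lam * factor + rng.standard_normal(n)
    stat = crosssubject_covariance_map(flat_cohort(Y), seed)
    thr = fwe_threshold(stat, 0.05)
    assert thr.pos_mask.ravel()[10]


def test_covariate_removes_planted_global_effect(rng):
    """Regressing out a planted whole-volume scaling kills the spurious t."""
    n, V = 80, 40
    g = rng.standard_normal(n)  # global scaling factor
    Y = 0.8 * g[:, None] + rng.standard_normal((n, V)) * 0.3
    seed = 0.8 * g + rng.standard_normal(n) * 0.3
    naive = crosssubject_covariance_map(flat_cohort(Y), seed)
    adj = crosssubject_covariance_map(flat_cohort(Y), seed, covariates=g[:, None])
    thr = fwe_threshold(adj, 0.05)
    assert fwe_threshold(naive, 0.05).pos_mask.any()
    assert not thr.pos_mask.any() and not thr.neg_mask.any()


# ---------------------------------------------------------------------------
# encode_covariates
# ---------------------------------------------------------------------------

def test_encode_covariates_centered_dummies():
    import pandas as pd

    df = pd.DataFrame(
        {"subject_id": list("abcd"), "center": ["A", "A", "B", "B"],
         "sex": ["M", "F", "M", "F"], "age": [22.0, 31.0, 45.0, 58.0]}
    )
    Z, names = encode_covariates(df)
    assert Z.shape == (4, 3)
    assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    assert names == ["center_B", "sex_M", "age"]


def test_encode_covariates_drops_constant_column():
    import pandas as pd

    df = pd.DataFrame(
        {"subject_id": list("abcd"), "center": ["A"] * 4,
         "sex": ["M", "F", "M", "F"], "age": [20.0, 30.0, 40.0, 50.0]}
    )
    Z, names = encode_covariates(df, extra={"zeros": np.zeros(4)})
    assert "zeros" not in names and not any(n.startswith("center") for n in names)


# ---------------------------------------------------------------------------
# fwe_threshold
# ---------------------------------------------------------------------------

def test_fwe_single_voxel_is_uncorrected():
    from scipy import stats as ss

    grid = centered_grid(shape=(1, 1, 1))
    sm = StatMap(grid=grid, t_values=np.zeros((1, 1, 1)), df=28)
    thr = fwe_threshold(sm, 0.05)
    assert thr.t_crit == pytest.approx(ss.t.ppf(0.975, 28), rel=1e-12)


def test_fwe_quantile_matches_independent_inversion():
    """Bonferroni critical t via bisection on the CDF from the incomplete beta."""
    from scipy import special

    V, df, alpha = 1000, 298, 0.05
    grid = centered_grid(shape=(10, 10, 10))
    sm = StatMap(grid=grid, t_values=np.zeros((10, 10, 10)), df=df)
    thr = fwe_threshold(sm, alpha)

    def t_sf(x):  # upper tail via regularized incomplete beta
        return 0.5 * special.betainc(df / 2.0, 0.5, df / (df + x * x))

    target = alpha / (2 * V)
    lo, hi = 0.0, 100.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if t_sf(mid) > target:
            lo = mid
        else:
            hi = mid
    assert thr.t_crit == pytest.approx((lo + hi) / 2, rel=1e-8)


def test_fwe_masks_disjoint_and_thresholded(rng):
    grid = centered_grid(shape=(6, 6, 6))
    sm = StatMap(grid=grid, t_values=rng.standard_normal(grid.shape) * 4, df=30)
    thr = fwe_threshold(sm, 0.05)
    assert not (thr.pos_mask & thr.neg_mask).any()
    assert (sm.t_values[thr.pos_mask] >= thr.t_crit).all()
    assert (sm.t_values[thr.neg_mask] <= -thr.t_crit).all()


# ---------------------------------------------------------------------------
# cluster_table
# ---------------------------------------------------------------------------

def _thr_from_t(t, grid, t_crit=2.0):
    sm = StatMap(grid=grid, t_values=t, df=20)
    from alffnet.glm import ThresholdedMap

    return ThresholdedMap(
        source=sm, alpha_fwe=0.05, t_crit=t_crit,
        pos_mask=(t >= t_crit) & grid.brain_mask,
        neg_mask=(t <= -t_crit) & grid.brain_mask,
    )


def test_cluster_table_empty_masks():
    grid = centered_grid(shape=(5, 5, 5))
    assert cluster_table(_thr_from_t(np.zeros(grid.shape), grid)) == []


def test_cluster_table_two_blobs_sorted_by_size():
    grid = centered_grid(shape=(9, 9, 9))
    t = np.zeros(grid.shape)
    t[0, 0, 0:3] = 3.0          # 3-voxel blob
    t[5, 5, 2:7] = [3, 4, 5, 4, 3]  # 5-voxel blob, peak t=5 at (5,5,4)
    rows = cluster_table(_thr_from_t(t, grid), min_voxels=2)
    assert [r.voxel_count for r in rows] == [5, 3]
    assert rows[0].peak_t == 5.0
    assert rows[0].peak_mm == tuple(grid.voxel_to_mm(np.array([5, 5, 4])))


def test_cluster_table_min_voxels_filter():
    grid = centered_grid(shape=(5, 5, 5))
    t = np.zeros(grid.shape)
    t[2, 2, 2] = 10.0
    assert cluster_table(_thr_from_t(t, grid), min_voxels=2) == []


def test_cluster_table_26_connectivity_diagonal():
    grid = centered_grid(shape=(5, 5, 5))
    t = np.zeros(grid.shape)
    t[1, 1, 1] = t[2, 2, 2] = 3.0  # corner-adjacent -> one component
    rows = cluster_table(_thr_from_t(t, grid), min_voxels=1)
    assert len(rows) == 1 and rows[0].voxel_count == 2


def test_cluster_table_negative_components_reported():
    grid = centered_grid(shape=(5, 5, 5))
    t = np.zeros(grid.shape)
    t[1, 1, 1:4] = -5.0
    rows = cluster_table(_thr_from_t(t, grid), min_voxels=1)
    assert len(rows) == 1 and rows[0].peak_t == -5.0
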