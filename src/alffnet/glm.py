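"""The three network estimators and FWE thresholding.

* TS-ICN (time-series intrinsic connectivity network): within each subject,
  nuisance-residualized Pearson correlation between the seed's mean BOLD
  series and every voxel series, carried to the group as Fisher z and tested
  with a one-sample t (covariates: center, sex, age).
* ALFF-FCN (functional covariance network): across subjects, the t of the
  seed-ALFF regressor in a voxel-wise GLM on standardized ALFF
  (covariates: mean WM/CSF ALFF, center, sex, age).
* VBM-SCN (structural covariance network): the same across-subject engine on
  gray-matter volume (covariates: total cranial volume, whole GM volume,
  center, sex, age).

Family-wise error is controlled by Bonferroni over in-mask voxels: the
two-sided per-voxel level is alpha / V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearDesignError,
    DegenerateInputError,
    GridMismatchError,
    ParameterError,
)
from .grid import VolumeGrid
from .images import Bold4D, ScalarMap

__all__ = [
    "StatMap",
    "ThresholdedMap",
    "CohortMatrix",
    "encode_covariates",
    "subject_icn_map",
    "group_onesample_t",
    "crosssubject_covariance_map",
    "vbm_scn_map",
    "fwe_threshold",
]

logger = logging.getLogger(__name__)

T_CAP = 1e8  # finite stand-in for infinite t at zero residual variance
R_CLIP = 1.0 - 1e-7  # |r| clip before the Fisher transform
_RSS_TOL = 1e-24  # relative threshold for "zero" residual variance


@dataclass(frozen=True)
class StatMap:
    """Voxel-wise t statistics from one estimator for one seed."""

    grid: VolumeGrid
    t_values: np.ndarray
    df: int
    seed_name: str = ""
    estimator: str = ""
    degenerate_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_values, dtype=float)
        if t.shape != self.grid.shape:
            raise GridMismatchError(f"t shape {t.shape} != grid {self.grid.shape}")
        if self.df <= 0:
            raise ParameterError(f"df must be positive, got {self.df}")
        if not np.isfinite(t[self.grid.brain_mask]).all():
            raise ParameterError("non-finite t inside the brain mask")
        object.__setattr__(self, "t_values", t)
        object.__setattr__(self, "df", int(self.df))


@dataclass(frozen=True)
class ThresholdedMap:
    """FWE-thresholded StatMap with positive / negative significance masks."""

    source: StatMap
    alpha_fwe: float
    t_crit: float
    pos_mask: np.ndarray
    neg_mask: np.ndarray

    @property
    def grid(self) -> VolumeGrid:
        return self.source.grid


@dataclass(frozen=True)
class CohortMatrix:
    """subjects x in-mask-voxels matrix of one measure, aligned to a phenotype.

    ``data[i]`` holds subject ``subject_ids[i]``'s values at
    ``grid.brain_mask`` voxels in C order.
    """

    grid: VolumeGrid
    data: np.ndarray
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != self.grid.n_brain_voxels:
            raise GridMismatchError(
                f"cohort matrix shape {data.shape} != (n, {self.grid.n_brain_voxels})"
            )
        if data.shape[0] != len(self.subject_ids):
            raise ParameterError("row count != number of subject ids")
        if not np.isfinite(data).all():
            raise ParameterError("cohort matrix contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def to_volume(self, row: np.ndarray) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=float)
        out[self.grid.brain_mask] = row
        return out

    @classmethod
    def from_maps(cls, maps, subject_ids) -> "CohortMatrix":
        grid = maps[0].grid
        rows = []
        for m in maps:
            grid.require_match(m.grid, what="cohort map")
            rows.append(m.values[grid.brain_mask])
        return cls(grid=grid, data=np.asarray(rows), subject_ids=tuple(subject_ids))


# ---------------------------------------------------------------------------
# Design helpers
# ---------------------------------------------------------------------------

def encode_covariates(
    phenotype: pd.DataFrame,
    categorical: tuple[str, ...] = ("center", "sex"),
    numeric: tuple[str, ...] = ("age",),
    extra: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build a mean-centered covariate matrix from a phenotype table.

    Categorical columns become drop-first dummy columns; numeric columns and
    ``extra`` vectors are used as-is.  Everything is mean-centered so the
    intercept of a model that includes these covariates is the covariate-
    adjusted group mean.  Constant (zero-variance) columns are dropped with a
    log note rather than raising.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for c in categorical:
        dummies = pd.get_dummies(phenotype[c].astype(str), prefix=c, drop_first=True)
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy(dtype=float))
            names.append(name)
    for c in numeric:
        cols.append(phenotype[c].to_numpy(dtype=float))
        names.append(c)
    for name, vec in (extra or {}).items():
        cols.append(np.asarray(vec, dtype=float))
        names.append(name)
    keep_cols, keep_names = [], []
    for col, name in zip(cols, names):
        if np.ptp(col) == 0:
            logger.info("dropping constant covariate column %r", name)
            continue
        keep_cols.append(col - col.mean())
        keep_names.append(name)
    if not keep_cols:
        return np.empty((len(phenotype), 0)), []
    Z = np.column_stack(keep_cols)
    _check_full_rank(np.column_stack([np.ones(len(Z)), Z]), ["intercept"] + keep_names)
    return Z, keep_names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal offending column by greedy elimination
        bad = []
        base_rank = 0
        kept: list[int] = []
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, kept + [j]])
            if r > base_rank:
                kept.append(j)
                base_rank = r
            else:
                bad.append(names[j] if j < len(names) else f"col{j}")
        raise CollinearDesignError(f"design is rank deficient; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# Core fitting engine
# ---------------------------------------------------------------------------

def _fit_coefficient_t(
    Y: np.ndarray, X: np.ndarray, coef_index: int, names: list[str]
) -> tuple[np.ndarray, int, np.ndarray]:
    """t of one coefficient of ``Y ~ X`` fitted per column of Y.

    Returns (t per voxel, df, degenerate flags).  Voxels with (numerically)
    zero residual variance get t = 0 when the coefficient estimate is 0 and
    +/-T_CAP otherwise, and are flagged.
    """
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ParameterError(f"insufficient degrees of freedom: n={n}, p={p}")
    _check_full_rank(X, names)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
    degenerate = rss <= _RSS_TOL * scale
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[coef_index, coef_index], 0.0))
    b = beta[coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / np.where(se > 0, se, 1.0), 0.0)
    if degenerate.any():
        nz = degenerate & (np.abs(b) > 0)
        t[degenerate] = 0.0
        t[nz] = np.sign(b[nz]) * T_CAP
        logger.warning(
            "%d voxel(s) with zero residual variance; t capped/zeroed", int(degenerate.sum())
        )
    t = np.clip(t, -T_CAP, T_CAP)
    return t, df, degenerate


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of Y (columns) against the column space of X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def subject_icn_map(
    bold: Bold4D,
    seed_mask: np.ndarray,
    nuisance: np.ndarray | None = None,
    nuisance_names: list[str] | None = None,
) -> ScalarMap:
    """Subject-level seed connectivity: Fisher-z correlation map.

    The seed's mean series and every voxel series are residualized against
    [intercept | nuisance], Pearson r of the residuals is computed per voxel
    and returned as z = atanh(r) with |r| clipped to 1 - 1e-7.  Voxels whose
    residual series is constant get z = 0 (logged).
    """
    grid = bold.grid
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ParameterError("subject_icn_map: empty seed mask")
    T = bold.n_timepoints
    if nuisance is None or nuisance.size == 0:
        X = np.ones((T, 1))
        names = ["intercept"]
    else:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != T:
            raise ParameterError("nuisance rows must equal the number of timepoints")
        names = ["intercept"] + (
            nuisance_names or [f"nuis{j}" for j in range(nuisance.shape[1])]
        )
        X = np.column_stack([np.ones(T), nuisance])
        if T <= X.shape[1] + 3:
            raise ParameterError("too few timepoints for the nuisance model")
        _check_full_rank(X, names)

    Y = bold.data[:, grid.brain_mask]
    seed = Y[:, seed_mask[grid.brain_mask]].mean(axis=1, keepdims=True)
    stacked = np.column_stack([seed, Y])
    R = _residualize(stacked, X)
    seed_r, vox_r = R[:, 0], R[:, 1:]
    # a residual that is numerically zero relative to the original series is
    # "constant after nuisance regression", not a real signal
    orig_norm = np.linalg.norm(stacked - stacked.mean(axis=0, keepdims=True), axis=0)
    tol = 1e-7 * np.maximum(orig_norm, 1e-300)
    seed_norm = float(np.linalg.norm(seed_r))
    vox_norm = np.linalg.norm(vox_r, axis=0)
    ok = (seed_norm > tol[0]) & (vox_norm > tol[1:])
    if seed_norm <= tol[0]:
        logger.warning("seed series constant after nuisance regression; z map is 0")
        r = np.zeros(Y.shape[1])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(ok, (seed_r @ vox_r) / (seed_norm * np.where(ok, vox_norm, 1.0)), 0.0)
        n_const = int((~ok).sum())
        if n_const:
            logger.info("%d voxel(s) constant after nuisance regression; z set to 0", n_const)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    vol = np.zeros(grid.shape)
    vol[grid.brain_mask] = z
    return ScalarMap(grid=grid, values=vol, name="icn_z")


def group_onesample_t(
    subject_maps,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    seed_name: str = "",
    estimator: str = "TS-ICN",
) -> StatMap:
    """Random-effects one-sample t of the intercept, per voxel.

    ``subject_maps`` is a list of ScalarMaps (or an (n, V) in-mask array plus
    a grid via CohortMatrix).  Covariates are mean-centered internally so the
    intercept is the tested group effect; df = n - 1 - c.
    """
    if isinstance(subject_maps, CohortMatrix):
        cohort = subject_maps
    else:
        cohort = CohortMatrix.from_maps(
            subject_maps, [f"s{i}" for i in range(len(subject_maps))]
        )
    n = cohort.n_subjects
    if covariates is None or covariates.size == 0:
        Z = np.empty((n, 0))
        names = ["intercept"]
    else:
        Z = np.asarray(covariates, dtype=float)
        Z = Z - Z.mean(axis=0, keepdims=True)
        names = ["intercept"] + (
            covariate_names or [f"cov{j}" for j in range(Z.shape[1])]
        )
    if n <= Z.shape[1] + 1:
        raise ParameterError(
            f"insufficient subjects: n={n} with {Z.shape[1]} covariates"
        )
    X = np.column_stack([np.ones(n), Z])
    t, df, degen = _fit_coefficient_t(cohort.data, X, coef_index=0, names=names)
    vol = np.zeros(cohort.grid.shape)
    vol[cohort.grid.brain_mask] = t
    dmask = np.zeros(cohort.grid.shape, dtype=bool)
    dmask[cohort.grid.brain_mask] = degen
    return StatMap(
        grid=cohort.grid, t_values=vol, df=df, seed_name=seed_name,
        estimator=estimator, degenerate_mask=dmask,
    )


def crosssubject_covariance_map(
    matrix: CohortMatrix,
    seed_values: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    seed_name: str = "",
    estimator: str = "ALFF-FCN",
) -> StatMap:
    """Across-subject covariance network: t of the seed regressor per voxel.

    Fits value_v ~ 1 + seed + covariates per voxel; df = n - 2 - c.  This is
    the partial-correlation t of (value_v, seed | covariates).
    """
    seed = np.asarray(seed_values, dtype=float)
    n = matrix.n_subjects
    if seed.shape != (n,):
        raise ParameterError(f"seed_values must have shape ({n},)")
    if np.ptp(seed) == 0:
        raise DegenerateInputError("seed values are constant across subjects")
    if covariates is None or covariates.size == 0:
        Z = np.empty((n, 0))
        names = ["intercept", "seed"]
    else:
        Z = np.asarray(covariates, dtype=float)
        Z = Z - Z.mean(axis=0, keepdims=True)
        names = ["intercept", "seed"] + (
            covariate_names or [f"cov{j}" for j in range(Z.shape[1])]
        )
    if n <= Z.shape[1] + 3:
        raise ParameterError(
            f"insufficient subjects: n={n} with {Z.shape[1]} covariates"
        )
    X = np.column_stack([np.ones(n), seed - seed.mean(), Z])
    t, df, degen = _fit_coefficient_t(matrix.data, X, coef_index=1, names=names)
    vol = np.zeros(matrix.grid.shape)
    vol[matrix.grid.brain_mask] = t
    dmask = np.zeros(matrix.grid.shape, dtype=bool)
    dmask[matrix.grid.brain_mask] = degen
    return StatMap(
        grid=matrix.grid, t_values=vol, df=df, seed_name=seed_name,
        estimator=estimator, degenerate_mask=dmask,
    )


def vbm_scn_map(
    gm_matrix: CohortMatrix,
    roi_gm_means: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    seed_name: str = "",
) -> StatMap:
    """Structural covariance network map; same engine as the ALFF-FCN."""
    return crosssubject_covariance_map(
        gm_matrix,
        roi_gm_means,
        covariates=covariates,
        covariate_names=covariate_names,
        seed_name=seed_name,
        estimator="VBM-SCN",
    )


def fwe_threshold(stat: StatMap, alpha: float = 0.05) -> ThresholdedMap:
    """Bonferroni FWE threshold: two-sided per-voxel level alpha / V.

    t_crit is the upper alpha/(2V) quantile of Student t with the map's df,
    where V is the number of in-mask voxels.
    """
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    V = stat.grid.n_brain_voxels
    t_crit = float(stats.t.ppf(1.0 - alpha / (2.0 * V), stat.df))
    inb = stat.grid.brain_mask
    pos = (stat.t_values >= t_crit) & inb
    neg = (stat.t_values <= -t_crit) & inb
    return ThresholdedMap(
        source=stat, alpha_fwe=alpha, t_crit=t_crit, pos_mask=pos, neg_mask=neg
    )
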