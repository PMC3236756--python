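"""Study orchestration: ALFF maps -> three estimators per seed -> FWE
thresholding -> hierarchical clustering -> conjunctions -> dichotomy report.

Each stage reads its inputs from the study layout on disk and writes its
outputs back, so any stage can be re-run from saved intermediates.  A
manifest records every parameter and a SHA-256 checksum of every output.

Output layout under ``config.out_dir``::

    alff/<subject>_alff.nii[.json]   standardized ALFF maps
    alff/nuisance_alff.tsv           per-subject mean WM / CSF ALFF
    icn/zstack_<seed>.npy            subjects x voxels Fisher-z stacks
    {icn,fcn,scn}/stat_<seed>.nii    t-maps (+ .json provenance sidecars)
    {icn,fcn,scn}/clusters_<seed>.tsv
    cluster/<estimator>_{r,d}.tsv, _dendrogram.json, _partition.json
    conjoin/...                      conjunction masks (pos/neg NIfTI pairs)
    report/dichotomy.json            two-system statistics
    manifest.json
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alff import compute_alff_map, standardize_alff
from .clusters import cluster_table, cluster_table_frame
from .errors import ConfigurationError, ValidationError
from .glm import (
    CohortMatrix,
    StatMap,
    crosssubject_covariance_map,
    encode_covariates,
    fwe_threshold,
    group_onesample_t,
    subject_icn_map,
    vbm_scn_map,
)
from .grid import all_seeds, load_roi_sets, sphere_roi_mask
from .images import (
    extract_roi_mean,
    load_bold,
    load_grid,
    load_scalar,
    read_phenotype,
    save_scalar,
)
from .signal import bandpass_filter, spatial_smooth
from .topology import (
    conjunction_inter_set,
    conjunction_intra_set,
    dichotomy_statistics,
    hierarchical_cluster,
    map_distance_matrix,
    ts_icn_dichotomy,
)

__all__ = ["StudyConfig", "ValidationReport", "validate_inputs", "run_study"]

logger = logging.getLogger(__name__)

ESTIMATORS = ("icn", "fcn", "scn")


@dataclass
class StudyConfig:
    """Paths and parameters of one study run.

    Parameter defaults are the method's standard settings: 0.01-0.08 Hz
    band, 8 mm FWHM smoothing, Bonferroni FWE at alpha 0.05, 2-of-3 /
    8-of-9 conjunctions with the SN set sign-flipped, d = 1 - r
    dissimilarity with average linkage cut at 0.4.
    """

    bold_dir: str
    gm_dir: str
    brain_mask: str
    phenotype: str
    roi_file: str
    out_dir: str
    wm_mask: str | None = None
    csf_mask: str | None = None
    motion_dir: str | None = None

    band_hz: tuple[float, float] = (0.01, 0.08)
    fwhm_mm: float = 8.0
    alpha_fwe: float = 0.05
    k_intra: int = 2
    k_inter: int = 8
    flip_set: str = "SN"
    dissimilarity: str = "one_minus_r"
    linkage: str = "average"
    cut_height: float = 0.4
    global_signal: bool = True
    detrend: bool = True
    min_cluster_voxels: int = 5
    tr_seconds: float | None = None  # override when absent from headers
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.band_hz = tuple(cfg.band_hz)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d


@dataclass
class ValidationReport:
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


@dataclass
class StudyContext:
    config: StudyConfig
    grid: "object"
    wm: np.ndarray | None
    csf: np.ndarray | None
    phenotype: pd.DataFrame
    roi_sets: list
    seeds: list          # (set_label, SeedROI)
    seed_masks: dict     # name -> voxel mask
    out: Path


# ---------------------------------------------------------------------------
# Context / validation
# ---------------------------------------------------------------------------

def _subject_paths(cfg: StudyConfig, subject_id: str) -> tuple[Path, Path]:
    return (
        Path(cfg.bold_dir) / f"{subject_id}_bold.nii",
        Path(cfg.gm_dir) / f"{subject_id}_gm.nii",
    )


def build_context(cfg: StudyConfig) -> StudyContext:
    grid = load_grid(cfg.brain_mask)
    wm = csf = None
    if cfg.wm_mask:
        wm = load_grid(cfg.wm_mask).brain_mask
    if cfg.csf_mask:
        csf = load_grid(cfg.csf_mask).brain_mask
    phenotype = read_phenotype(cfg.phenotype)
    roi_sets = load_roi_sets(cfg.roi_file)
    seeds = all_seeds(roi_sets)
    seed_masks = {roi.name: sphere_roi_mask(roi, grid) for _, roi in seeds}
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return StudyContext(
        config=cfg, grid=grid, wm=wm, csf=csf, phenotype=phenotype,
        roi_sets=roi_sets, seeds=seeds, seed_masks=seed_masks, out=out,
    )


def validate_inputs(cfg: StudyConfig) -> ValidationReport:
    """Check grid agreement, phenotype completeness, ROI-in-brain and TR.

    Never mutates data; aggregates human-readable failures.
    """
    rep = ValidationReport()
    for name in ("bold_dir", "gm_dir", "brain_mask", "phenotype", "roi_file"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            rep.failures.append(f"{name}: path {p!r} does not exist")
    if rep.failures:
        return rep
    try:
        grid = load_grid(cfg.brain_mask)
    except Exception as exc:  # noqa: BLE001 - aggregate, don't raise
        rep.failures.append(f"brain_mask: {exc}")
        return rep
    for name in ("wm_mask", "csf_mask"):
        p = getattr(cfg, name)
        if p:
            try:
                grid.require_match(load_grid(p), what=name)
            except Exception as exc:
                rep.failures.append(f"{name}: {exc}")
    try:
        phenotype = read_phenotype(cfg.phenotype)
    except Exception as exc:
        rep.failures.append(f"phenotype: {exc}")
        return rep
    try:
        roi_sets = load_roi_sets(cfg.roi_file)
        for _, roi in all_seeds(roi_sets):
            try:
                sphere_roi_mask(roi, grid)
            except Exception as exc:
                rep.failures.append(f"ROI {roi.name}: {exc}")
    except Exception as exc:
        rep.failures.append(f"roi_file: {exc}")
    for sid in phenotype["subject_id"]:
        bold_p, gm_p = _subject_paths(cfg, sid)
        if not bold_p.exists():
            rep.failures.append(f"subject {sid}: missing BOLD file {bold_p}")
        if not gm_p.exists():
            rep.failures.append(f"subject {sid}: missing GM file {gm_p}")
    if phenotype.shape[0] > 0 and not rep.failures:
        sid = phenotype["subject_id"].iloc[0]
        bold_p, _ = _subject_paths(cfg, sid)
        try:
            b = load_bold(bold_p, grid=grid, tr_seconds=cfg.tr_seconds)
            if b.tr_seconds <= 0:
                rep.failures.append(f"subject {sid}: non-positive TR")
        except Exception as exc:
            rep.failures.append(f"subject {sid}: {exc}")
    return rep


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _load_preprocessed_bold(ctx: StudyContext, sid: str):
    cfg = ctx.config
    bold_p, _ = _subject_paths(cfg, sid)
    bold = load_bold(bold_p, grid=ctx.grid, tr_seconds=cfg.tr_seconds)
    if cfg.fwhm_mm > 0:
        bold = spatial_smooth(bold, cfg.fwhm_mm)  # smooth, then filter
    return bandpass_filter(bold, *cfg.band_hz, detrend=cfg.detrend)


def _save_statmap(stat: StatMap, thr, path_base: Path, extra: dict | None = None):
    sidecar = {
        "estimator": stat.estimator,
        "seed": stat.seed_name,
        "df": stat.df,
        "alpha_fwe": thr.alpha_fwe,
        "t_crit": thr.t_crit,
        "alffnet_version": __version__,
    }
    if extra:
        sidecar.update(extra)
    save_scalar(_as_scalar(stat), str(path_base) + ".nii", sidecar=sidecar)


def _as_scalar(stat: StatMap):
    from .images import ScalarMap

    return ScalarMap(grid=stat.grid, values=stat.t_values, name=stat.seed_name)


def load_statmap(path_base: Path, grid) -> StatMap:
    """Re-load a saved t-map with its provenance sidecar."""
    m = load_scalar(str(path_base) + ".nii", grid=grid)
    meta = json.loads(Path(str(path_base) + ".json").read_text())
    return StatMap(
        grid=grid, t_values=m.values, df=int(meta["df"]),
        seed_name=meta.get("seed", ""), estimator=meta.get("estimator", ""),
    )


def _estimator_dir(ctx: StudyContext, est: str) -> Path:
    d = ctx.out / est
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_seed_outputs(ctx: StudyContext, est: str, stat: StatMap):
    cfg = ctx.config
    thr = fwe_threshold(stat, cfg.alpha_fwe)
    d = _estimator_dir(ctx, est)
    _save_statmap(stat, thr, d / f"stat_{stat.seed_name}",
                  extra={"covariates": _covariate_names(ctx, est)})
    rows = cluster_table(thr, min_voxels=cfg.min_cluster_voxels)
    cluster_table_frame(rows).to_csv(
        d / f"clusters_{stat.seed_name}.tsv", sep="\t", index=False
    )
    return thr


def _covariate_names(ctx: StudyContext, est: str) -> list[str]:
    base = ["center", "sex", "age"]
    if est == "fcn":
        return ["wm_alff", "csf_alff"] + base
    if est == "scn":
        return ["tcv", "gmv"] + base
    return base


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_alff(ctx: StudyContext) -> None:
    """Per subject: smooth, band-pass, ALFF, standardize; save maps and the
    mean WM/CSF ALFF nuisance table."""
    cfg = ctx.config
    d = ctx.out / "alff"
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid in ctx.phenotype["subject_id"]:
        bold = _load_preprocessed_bold(ctx, sid)
        alff = standardize_alff(compute_alff_map(bold, cfg.band_hz))
        save_scalar(
            _as_scalar_map(alff), d / f"{sid}_alff.nii",
            sidecar={
                "band_hz": list(cfg.band_hz), "tr_seconds": bold.tr_seconds,
                "standardized": True, "fwhm_mm": cfg.fwhm_mm,
            },
        )
        row = {"subject_id": sid}
        if ctx.wm is not None and ctx.wm.any():
            row["wm_alff"] = extract_roi_mean(_as_scalar_map(alff), ctx.wm)
        if ctx.csf is not None and ctx.csf.any():
            row["csf_alff"] = extract_roi_mean(_as_scalar_map(alff), ctx.csf)
        rows.append(row)
    pd.DataFrame(rows).to_csv(d / "nuisance_alff.tsv", sep="\t", index=False)


def _as_scalar_map(alff):
    from .images import ScalarMap

    return ScalarMap(grid=alff.grid, values=alff.values, name="alff")


def _load_alff_cohort(ctx: StudyContext) -> tuple[CohortMatrix, pd.DataFrame]:
    d = ctx.out / "alff"
    maps, ids = [], []
    for sid in ctx.phenotype["subject_id"]:
        maps.append(load_scalar(d / f"{sid}_alff.nii", grid=ctx.grid))
        ids.append(sid)
    nuis = pd.read_csv(d / "nuisance_alff.tsv", sep="\t", dtype={"subject_id": str})
    return CohortMatrix.from_maps(maps, ids), nuis


def _subject_nuisance(ctx: StudyContext, bold, sid: str) -> tuple[np.ndarray, list[str]]:
    cfg = ctx.config
    cols, names = [], []
    if ctx.wm is not None and ctx.wm.any():
        cols.append(extract_roi_mean(bold, ctx.wm))
        names.append("wm")
    if ctx.csf is not None and ctx.csf.any():
        cols.append(extract_roi_mean(bold, ctx.csf))
        names.append("csf")
    if cfg.global_signal:
        cols.append(extract_roi_mean(bold, ctx.grid.brain_mask))
        names.append("global")
    if cfg.motion_dir:
        mot_p = Path(cfg.motion_dir) / f"{sid}_motion.txt"
        if mot_p.exists():
            mot = np.atleast_2d(np.loadtxt(mot_p))
            if mot.shape[0] != bold.n_timepoints:
                mot = mot.T
            for j in range(mot.shape[1]):
                cols.append(mot[:, j])
                names.append(f"motion{j}")
    keep, keep_names = [], []
    for c, n in zip(cols, names):
        if np.ptp(c) > 0:
            keep.append(c)
            keep_names.append(n)
        else:
            logger.info("subject %s: dropping constant nuisance column %r", sid, n)
    if not keep:
        return np.empty((bold.n_timepoints, 0)), []
    return np.column_stack(keep), keep_names


def stage_icn(ctx: StudyContext) -> None:
    """Subject-level seed correlation (Fisher z) and group one-sample t."""
    cfg = ctx.config
    d = _estimator_dir(ctx, "icn")
    n = len(ctx.phenotype)
    V = ctx.grid.n_brain_voxels
    stacks = {name: np.zeros((n, V), dtype=np.float32) for name in ctx.seed_masks}
    for i, sid in enumerate(ctx.phenotype["subject_id"]):
        bold = _load_preprocessed_bold(ctx, sid)
        nuis, nuis_names = _subject_nuisance(ctx, bold, sid)
        for name, mask in ctx.seed_masks.items():
            z = subject_icn_map(bold, mask, nuisance=nuis, nuisance_names=nuis_names)
            stacks[name][i] = z.values[ctx.grid.brain_mask]
    ids = list(ctx.phenotype["subject_id"])
    (d / "subjects.json").write_text(json.dumps(ids))
    Z, znames = encode_covariates(ctx.phenotype)
    for name, stack in stacks.items():
        np.save(d / f"zstack_{name}.npy", stack)
        cohort = CohortMatrix(grid=ctx.grid, data=stack.astype(float), subject_ids=ids)
        stat = group_onesample_t(
            cohort, covariates=Z, covariate_names=znames,
            seed_name=name, estimator="TS-ICN",
        )
        _write_seed_outputs(ctx, "icn", stat)


def stage_fcn(ctx: StudyContext) -> None:
    """Across-subject ALFF covariance networks for every seed."""
    cohort, nuis = _load_alff_cohort(ctx)
    extra = {}
    for c in ("wm_alff", "csf_alff"):
        if c in nuis.columns:
            extra[c] = nuis[c].to_numpy(float)
    Z, names = encode_covariates(ctx.phenotype, extra=extra)
    inb = ctx.grid.brain_mask
    for name, mask in ctx.seed_masks.items():
        sel = mask[inb]
        seed_vals = cohort.data[:, sel].mean(axis=1)
        stat = crosssubject_covariance_map(
            cohort, seed_vals, covariates=Z, covariate_names=names,
            seed_name=name, estimator="ALFF-FCN",
        )
        _write_seed_outputs(ctx, "fcn", stat)


def _load_gm_cohort(ctx: StudyContext) -> CohortMatrix:
    cfg = ctx.config
    maps, ids = [], []
    for sid in ctx.phenotype["subject_id"]:
        _, gm_p = _subject_paths(cfg, sid)
        m = load_scalar(gm_p, grid=ctx.grid)
        if cfg.fwhm_mm > 0:
            m = spatial_smooth(m, cfg.fwhm_mm)
        maps.append(m)
        ids.append(sid)
    return CohortMatrix.from_maps(maps, ids)


def stage_scn(ctx: StudyContext) -> None:
    """Across-subject gray-matter covariance networks for every seed."""
    cohort = _load_gm_cohort(ctx)
    extra = {}
    if "tcv" in ctx.phenotype.columns and ctx.phenotype["tcv"].notna().all():
        extra["tcv"] = ctx.phenotype["tcv"].to_numpy(float)
    if "gmv" in ctx.phenotype.columns and ctx.phenotype["gmv"].notna().all():
        extra["gmv"] = ctx.phenotype["gmv"].to_numpy(float)
    else:
        voxel_vol = float(np.prod(ctx.grid.voxel_sizes_mm))
        extra["gmv"] = cohort.data.sum(axis=1) * voxel_vol
    Z, names = encode_covariates(ctx.phenotype, extra=extra)
    inb = ctx.grid.brain_mask
    for name, mask in ctx.seed_masks.items():
        sel = mask[inb]
        seed_vals = cohort.data[:, sel].mean(axis=1)
        stat = vbm_scn_map(
            cohort, seed_vals, covariates=Z, covariate_names=names, seed_name=name
        )
        _write_seed_outputs(ctx, "scn", stat)


def _load_estimator_maps(ctx: StudyContext, est: str) -> list[StatMap]:
    d = ctx.out / est
    return [
        load_statmap(d / f"stat_{roi.name}", ctx.grid) for _, roi in ctx.seeds
    ]


def stage_cluster(ctx: StudyContext) -> dict:
    """Spatial-correlation distance matrices + dendrograms per estimator."""
    cfg = ctx.config
    d = ctx.out / "cluster"
    d.mkdir(parents=True, exist_ok=True)
    partitions = {}
    for est in ESTIMATORS:
        maps = _load_estimator_maps(ctx, est)
        dm = map_distance_matrix(maps, formula=cfg.dissimilarity)
        pd.DataFrame(dm.r, index=dm.labels, columns=dm.labels).to_csv(
            d / f"{est}_r.tsv", sep="\t"
        )
        pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(
            d / f"{est}_d.tsv", sep="\t"
        )
        dend, part = hierarchical_cluster(dm, method=cfg.linkage, cut_height=cfg.cut_height)
        (d / f"{est}_dendrogram.json").write_text(
            json.dumps({"labels": list(dend.labels), "method": dend.method,
                        "merges": dend.merges.tolist()}, sort_keys=True)
        )
        (d / f"{est}_partition.json").write_text(
            json.dumps({"cut_height": cfg.cut_height, "partition": part,
                        "n_clusters": len(set(part.values()))}, sort_keys=True)
        )
        partitions[est] = part
    return partitions


def _save_conjunction(ctx: StudyContext, cj, stem: Path):
    from .images import save_mask

    save_mask(cj.pos_mask, ctx.grid, str(stem) + "_pos.nii")
    save_mask(cj.neg_mask, ctx.grid, str(stem) + "_neg.nii")
    save_scalar(
        _as_scalar_from(ctx.grid, cj.mean_t), str(stem) + "_meant.nii",
        sidecar={"k": cj.k, "n": cj.n, "flip_set": cj.flip_set},
    )


def _as_scalar_from(grid, values):
    from .images import ScalarMap

    return ScalarMap(grid=grid, values=values, name="mean_t")


def stage_conjoin(ctx: StudyContext) -> dict:
    """Intra-set conjunctions (FCN, ICN), the inter-set FCN conjunction and
    the TS-ICN dichotomy."""
    cfg = ctx.config
    d = ctx.out / "conjoin"
    d.mkdir(parents=True, exist_ok=True)
    results = {}
    thr_by_set_fcn = {}
    for est in ("fcn", "icn"):
        maps = _load_estimator_maps(ctx, est)
        by_set: dict[str, list] = {}
        for (set_label, roi), stat in zip(ctx.seeds, maps):
            by_set.setdefault(set_label, []).append(fwe_threshold(stat, cfg.alpha_fwe))
        for set_label, thr_maps in by_set.items():
            cj = conjunction_intra_set(thr_maps, k=cfg.k_intra)
            _save_conjunction(ctx, cj, d / f"{est}_intra_{set_label}")
        if est == "fcn":
            thr_by_set_fcn = by_set
    inter = conjunction_inter_set(thr_by_set_fcn, flip_set=cfg.flip_set, k=cfg.k_inter)
    _save_conjunction(ctx, inter, d / "fcn_inter")
    results["fcn_inter"] = inter

    # TS-ICN dichotomy from the saved per-subject z stacks
    icn_dir = ctx.out / "icn"
    ids = json.loads((icn_dir / "subjects.json").read_text())
    by_set_subject_maps: dict[str, list] = {}
    from .images import ScalarMap

    for set_label, roi in ctx.seeds:
        if set_label not in ("DMN", "TPN"):
            continue
        stack = np.load(icn_dir / f"zstack_{roi.name}.npy")
        maps = []
        for i in range(stack.shape[0]):
            vol = np.zeros(ctx.grid.shape)
            vol[ctx.grid.brain_mask] = stack[i]
            maps.append(ScalarMap(grid=ctx.grid, values=vol, name=roi.name))
        by_set_subject_maps.setdefault(set_label, []).append(maps)
    if {"DMN", "TPN"} <= set(by_set_subject_maps):
        Z, znames = encode_covariates(ctx.phenotype)
        stat, thr = ts_icn_dichotomy(
            by_set_subject_maps, covariates=Z, alpha=cfg.alpha_fwe
        )
        _save_statmap(stat, thr, d / "icn_dichotomy")
        from .images import save_mask

        save_mask(thr.pos_mask, ctx.grid, d / "icn_dichotomy_pos.nii")
        save_mask(thr.neg_mask, ctx.grid, d / "icn_dichotomy_neg.nii")
        results["icn_dichotomy"] = thr
    return results


def stage_report(ctx: StudyContext) -> dict:
    """Dichotomy statistics over the inter-set conjunction systems."""
    d = ctx.out / "report"
    d.mkdir(parents=True, exist_ok=True)
    cohort, _ = _load_alff_cohort(ctx)
    conj = ctx.out / "conjoin"
    pos = load_grid(conj / "fcn_inter_pos.nii").brain_mask \
        if _mask_nonempty(conj / "fcn_inter_pos.nii") else None
    neg = load_grid(conj / "fcn_inter_neg.nii").brain_mask \
        if _mask_nonempty(conj / "fcn_inter_neg.nii") else None
    report: dict = {"alpha_fwe": ctx.config.alpha_fwe}
    if pos is not None and neg is not None:
        res = dichotomy_statistics(cohort, pos, neg)
        report["dichotomy"] = res.to_dict()
    else:
        report["dichotomy"] = None
        logger.warning("inter-set conjunction produced an empty system mask")
    (d / "dichotomy.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _mask_nonempty(path: Path) -> bool:
    import nibabel as nib

    return bool((np.asanyarray(nib.load(str(path)).dataobj) > 0).any())


def _manifest(ctx: StudyContext) -> dict:
    files = {}
    for p in sorted(ctx.out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(ctx.out))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return {
        "alffnet_version": __version__,
        "config": ctx.config.to_dict(),
        "n_subjects": int(len(ctx.phenotype)),
        "n_brain_voxels": ctx.grid.n_brain_voxels,
        "seeds": [roi.name for _, roi in ctx.seeds],
        "files": files,
    }


def run_study(config: StudyConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk).

    Fails fast with a :class:`ValidationError` listing every input problem.
    """
    report = validate_inputs(config)
    if not report.ok:
        raise ValidationError(
            "study inputs invalid:\n" + "\n".join(f"- {f}" for f in report.failures)
        )
    ctx = build_context(config)
    stage_alff(ctx)
    stage_icn(ctx)
    stage_fcn(ctx)
    stage_scn(ctx)
    stage_cluster(ctx)
    stage_conjoin(ctx)
    stage_report(ctx)
    manifest = _manifest(ctx)
    (ctx.out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
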