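"""Synthetic multi-subject cohorts with planted network structure.

The generator emulates the statistical structure the estimators are built to
detect, on a desk-scale grid:

* **Temporal modules** — every voxel's BOLD series is a band-limited sum of
  random-phase sinusoids on in-band DFT bins (so its ALFF is analytically
  tractable), mixed from a per-system latent signal (share ``rho_time``) and
  a voxel-unique signal, plus white noise.  The TPN latent is the negated
  DMN latent, planting the classic within-subject DMN/TPN anti-correlation;
  the sensory (SN) latent is independent.
* **Across-subject amplitude covariance** — each subject draws a high-level
  factor h (scaling DMN+TPN region amplitudes) and a low-level factor l
  (scaling SN amplitudes) from a bivariate normal with correlation
  ``system_corr`` (default -0.8): the two-system dichotomy.
* **Nuisance structure** — per-center, sex and age offsets on region
  amplitudes; WM and CSF compartments with independent signals; structurally
  covarying gray-matter maps with a planted global-scaling factor.

Everything is reproducible from (spec, seed); subjects can be generated one
at a time (:func:`iter_subjects`) so large cohorts never need to fit in
memory at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .grid import ROISet, SeedROI, VolumeGrid, sphere_roi_mask
from .images import Bold4D, ScalarMap, save_bold, save_mask, save_scalar
from .signal import band_bins

__all__ = [
    "RegionSpec",
    "SyntheticSpec",
    "SyntheticCohort",
    "SubjectRecord",
    "generate_cohort",
    "iter_subjects",
    "cohort_metadata",
    "build_geometry",
    "ground_truth_masks",
    "write_study",
]

# Desk-scale analogues of the nine canonical seeds: same three-per-system
# organisation, laid out non-overlapping inside a 72 mm box.
DEFAULT_REGIONS = (
    ("PCC", "DMN", (0.0, -20.0, 12.0)),
    ("DMPFC", "DMN", (0.0, 20.0, 12.0)),
    ("AG", "DMN", (-20.0, -12.0, 12.0)),
    ("DLPFC", "TPN", (20.0, 12.0, 12.0)),
    ("IPL", "TPN", (20.0, -12.0, 12.0)),
    ("FEF", "TPN", (-20.0, 12.0, 12.0)),
    ("SC", "SN", (0.0, -20.0, -15.0)),
    ("VC", "SN", (0.0, 20.0, -15.0)),
    ("AC", "SN", (20.0, 0.0, -15.0)),
)

HIGH_SYSTEMS = ("DMN", "TPN")
LOW_SYSTEMS = ("SN",)


@dataclass(frozen=True)
class RegionSpec:
    name: str
    system: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 6.0


def _default_regions() -> tuple[RegionSpec, ...]:
    return tuple(RegionSpec(n, s, c) for n, s, c in DEFAULT_REGIONS)


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the synthetic study.

    The defaults are the shipped desk-scale study: a 24^3 grid at 3 mm,
    nine radius-6 mm regions (three per system), 60 subjects, T=150 at
    TR=2 s, planted high/low system correlation -0.8.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_mm: float = 3.0
    brain_radius_mm: float = 33.0
    regions: tuple[RegionSpec, ...] = field(default_factory=_default_regions)
    wm_center_mm: tuple[float, float, float] = (-20.0, 0.0, -15.0)
    wm_radius_mm: float = 7.0
    csf_center_mm: tuple[float, float, float] = (0.0, 0.0, 27.0)
    csf_radius_mm: float = 6.0

    n_subjects: int = 60
    t_points: int = 150
    tr_seconds: float = 2.0
    band_hz: tuple[float, float] = (0.01, 0.08)

    # temporal structure
    rho_time: float = 0.5            # latent-signal variance share in regions
    temporal_noise_sd: float = 0.2   # white noise on every series

    # across-subject amplitude model
    amp_base: float = 1.0
    amp_loading: float = 0.12        # region amplitude = base*(1 + loading*factor)
    system_corr: float = -0.8        # corr of the high- and low-level factors
    amp_noise_sd: float = 0.02       # per-region amplitude noise
    background_amp: float = 1.0
    wm_amp: float = 0.8
    csf_amp: float = 0.6
    compartment_amp_jitter: float = 0.08  # relative across-subject WM/CSF variation

    # nuisance covariate effects on region/compartment amplitudes
    centers: tuple[str, ...] = ("A", "B")
    center_offsets: tuple[float, ...] = (0.0, 0.01)
    sex_offset: float = 0.01         # added for sex == "F"
    age_slope_per_year: float = 0.0005
    age_range: tuple[float, float] = (20.0, 60.0)

    # gray-matter (structural) model
    gm_region_base: float = 0.7
    gm_loading: float = 0.1          # per-system structural factor loading
    gm_background: float = 0.5
    gm_wm: float = 0.2
    gm_csf: float = 0.05
    gm_noise_sd: float = 0.02
    gm_global_sd: float = 0.04       # planted whole-GM scaling factor SD
    tcv_base_mm3: float = 1.5e6
    tcv_rel_sd: float = 0.03

    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.system_corr) > 1:
            raise ParameterError(
                f"system_corr={self.system_corr}: 2x2 factor correlation matrix "
                "is not positive semi-definite"
            )
        for sd in (self.temporal_noise_sd, self.amp_noise_sd, self.gm_noise_sd,
                   self.gm_global_sd, self.compartment_amp_jitter):
            if sd < 0:
                raise ParameterError("noise SDs must be >= 0")
        if not 0 <= self.rho_time <= 1:
            raise ParameterError(f"rho_time must be in [0, 1], got {self.rho_time}")
        if len(self.center_offsets) != len(self.centers):
            raise ParameterError("center_offsets must align with centers")
        object.__setattr__(self, "regions", tuple(self.regions))


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    bold: Bold4D
    gm: ScalarMap
    phenotype: dict


@dataclass(frozen=True)
class Geometry:
    grid: VolumeGrid
    region_masks: dict
    region_systems: dict
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    roi_sets: list


@dataclass(frozen=True)
class CohortDesign:
    """Per-subject planted quantities, drawn once from the metadata stream."""

    phenotype: pd.DataFrame
    factors: pd.DataFrame          # h, l, per-system structural factors, gm_scale
    region_amplitudes: pd.DataFrame  # subjects x regions
    wm_amplitudes: np.ndarray
    csf_amplitudes: np.ndarray


@dataclass(frozen=True)
class SyntheticCohort:
    spec: SyntheticSpec
    geometry: Geometry
    design: CohortDesign
    records: tuple[SubjectRecord, ...]

    @property
    def grid(self) -> VolumeGrid:
        return self.geometry.grid

    @property
    def phenotype(self) -> pd.DataFrame:
        return self.design.phenotype


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def build_geometry(spec: SyntheticSpec) -> Geometry:
    shape = tuple(spec.shape)
    v = spec.voxel_mm
    offset = -(np.asarray(shape) - 1) / 2.0 * v
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = offset
    centers = np.stack(
        np.meshgrid(*(np.arange(s) for s in shape), indexing="ij"), axis=-1
    ) * v + offset
    brain = np.linalg.norm(centers, axis=-1) <= spec.brain_radius_mm
    grid = VolumeGrid(shape=shape, affine=affine, brain_mask=brain)

    region_masks, region_systems = {}, {}
    occupied = np.zeros(shape, dtype=bool)
    for reg in spec.regions:
        roi = SeedROI(name=reg.name, center_mm=reg.center_mm, radius_mm=reg.radius_mm)
        m = sphere_roi_mask(roi, grid)
        if (m & occupied).any():
            raise ParameterError(f"region {reg.name} overlaps another region")
        occupied |= m
        region_masks[reg.name] = m
        region_systems[reg.name] = reg.system

    wm = sphere_roi_mask(
        SeedROI("WM", spec.wm_center_mm, spec.wm_radius_mm), grid
    ) & ~occupied
    csf = sphere_roi_mask(
        SeedROI("CSF", spec.csf_center_mm, spec.csf_radius_mm), grid
    ) & ~occupied & ~wm

    by_set: dict[str, list[SeedROI]] = {}
    for reg in spec.regions:
        by_set.setdefault(reg.system, []).append(
            SeedROI(reg.name, reg.center_mm, reg.radius_mm)
        )
    roi_sets = [ROISet(label, tuple(seeds)) for label, seeds in by_set.items()]
    return Geometry(
        grid=grid, region_masks=region_masks, region_systems=region_systems,
        wm_mask=wm, csf_mask=csf, roi_sets=roi_sets,
    )


def ground_truth_masks(cohort_or_geometry) -> tuple[np.ndarray, np.ndarray]:
    """Planted (high-level DMN+TPN, low-level SN) voxel masks; disjoint."""
    geo = getattr(cohort_or_geometry, "geometry", cohort_or_geometry)
    high = np.zeros(geo.grid.shape, dtype=bool)
    low = np.zeros(geo.grid.shape, dtype=bool)
    for name, mask in geo.region_masks.items():
        if geo.region_systems[name] in HIGH_SYSTEMS:
            high |= mask
        elif geo.region_systems[name] in LOW_SYSTEMS:
            low |= mask
    return high, low


# ---------------------------------------------------------------------------
# Design (per-subject planted quantities)
# ---------------------------------------------------------------------------

def cohort_metadata(spec: SyntheticSpec) -> CohortDesign:
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_subjects
    ids = [f"sub-{i + 1:04d}" for i in range(n)]
    center = rng.choice(list(spec.centers), size=n)
    sex = rng.choice(["M", "F"], size=n)
    age = rng.uniform(*spec.age_range, size=n)

    cov = np.array(
        [[1.0, spec.system_corr], [spec.system_corr, 1.0]]
    )
    hl = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="svd")
    h, l = hl[:, 0], hl[:, 1]

    systems = sorted({r.system for r in spec.regions})
    struct = {s: rng.standard_normal(n) for s in systems}
    gm_scale = 1.0 + spec.gm_global_sd * rng.standard_normal(n)
    tcv = spec.tcv_base_mm3 * (1.0 + spec.tcv_rel_sd * rng.standard_normal(n))

    offsets = dict(zip(spec.centers, spec.center_offsets))
    mean_age = float(np.mean(spec.age_range))
    covar_shift = (
        np.array([offsets[c] for c in center])
        + np.where(sex == "F", spec.sex_offset, 0.0)
        + spec.age_slope_per_year * (age - mean_age)
    )

    amp = {}
    for reg in spec.regions:
        f = h if reg.system in HIGH_SYSTEMS else l
        a = (
            spec.amp_base * (1.0 + spec.amp_loading * f)
            + covar_shift
            + spec.amp_noise_sd * rng.standard_normal(n)
        )
        amp[reg.name] = np.maximum(a, 0.05)
    wm_amp = spec.wm_amp * (
        1.0 + spec.compartment_amp_jitter * rng.standard_normal(n)
    ) + covar_shift
    csf_amp = spec.csf_amp * (
        1.0 + spec.compartment_amp_jitter * rng.standard_normal(n)
    ) + covar_shift

    phenotype = pd.DataFrame(
        {
            "subject_id": ids,
            "center": center,
            "sex": sex,
            "age": np.round(age, 2),
            "tcv": tcv,
        }
    )
    factors = pd.DataFrame(
        {"subject_id": ids, "high_factor": h, "low_factor": l, "gm_scale": gm_scale}
        | {f"struct_{s}": struct[s] for s in systems}
    )
    return CohortDesign(
        phenotype=phenotype,
        factors=factors,
        region_amplitudes=pd.DataFrame(amp, index=ids),
        wm_amplitudes=np.maximum(wm_amp, 0.05),
        csf_amplitudes=np.maximum(csf_amp, 0.05),
    )


# ---------------------------------------------------------------------------
# Per-subject data
# ---------------------------------------------------------------------------

def _bandlimited_unit(rng, bins: np.ndarray, n_time: int, n_series: int) -> np.ndarray:
    """(T, V) unit-RMS signals: equal-amplitude random-phase in-band sinusoids.

    Each retained DFT bin carries amplitude sqrt(2 / n_bins), so the series
    RMS is 1 and its per-bin amplitude spectrum is deterministic.
    """
    nb = bins.size
    amp = np.sqrt(2.0 / nb)
    spec = np.zeros((n_time // 2 + 1, n_series), dtype=complex)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(nb, n_series))
    spec[bins] = (amp * n_time / 2.0) * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n_time, axis=0)


def make_subject(spec: SyntheticSpec, geometry: Geometry, design: CohortDesign,
                 index: int) -> SubjectRecord:
    """Deterministically generate subject ``index`` of the cohort."""
    rng = np.random.default_rng([spec.seed, 1, index])
    grid = geometry.grid
    brain = grid.brain_mask
    n_vox = grid.n_brain_voxels
    T = spec.t_points
    bins = band_bins(T, spec.tr_seconds, *spec.band_hz)
    if bins.size == 0:
        raise ParameterError("no DFT bin in band for the synthetic spec")

    # latent module signals: TPN = -DMN (anti-correlated), SN independent
    latents = _bandlimited_unit(rng, bins, T, 3)  # DMN-drive, SN, WM/CSF drive
    module = {"DMN": latents[:, 0], "TPN": -latents[:, 0], "SN": latents[:, 1],
              "COMPARTMENT": latents[:, 2]}

    unique = _bandlimited_unit(rng, bins, T, n_vox)  # voxel-unique signals

    # amplitude and module assignment per in-brain voxel
    amp = np.full(n_vox, spec.background_amp)
    sig = unique.copy()  # background voxels: unique signal only
    w_mod = np.sqrt(spec.rho_time)
    w_unq = np.sqrt(1.0 - spec.rho_time)
    flat = lambda m: m[brain]
    for name, mask in geometry.region_masks.items():
        sel = flat(mask)
        system = geometry.region_systems[name]
        amp[sel] = design.region_amplitudes[name].iloc[index]
        sig[:, sel] = (
            w_mod * module[system][:, None] + w_unq * unique[:, sel]
        )
    for mask, a in ((geometry.wm_mask, design.wm_amplitudes[index]),
                    (geometry.csf_mask, design.csf_amplitudes[index])):
        sel = flat(mask)
        amp[sel] = a
        sig[:, sel] = w_mod * module["COMPARTMENT"][:, None] + w_unq * unique[:, sel]

    series = amp[None, :] * sig
    if spec.temporal_noise_sd > 0:
        series = series + spec.temporal_noise_sd * rng.standard_normal((T, n_vox))

    data = np.zeros((T, *grid.shape))
    data[:, brain] = series
    bold = Bold4D(grid=grid, data=data, tr_seconds=spec.tr_seconds)

    # gray-matter map
    gm = np.zeros(grid.shape)
    gm[brain] = spec.gm_background
    systems = sorted({r.system for r in spec.regions})
    struct = {s: design.factors[f"struct_{s}"].iloc[index] for s in systems}
    for name, mask in geometry.region_masks.items():
        system = geometry.region_systems[name]
        gm[mask] = spec.gm_region_base * (1.0 + spec.gm_loading * struct[system])
    gm[geometry.wm_mask] = spec.gm_wm
    gm[geometry.csf_mask] = spec.gm_csf
    gm_scale = design.factors["gm_scale"].iloc[index]
    noise = np.zeros(grid.shape)
    noise[brain] = spec.gm_noise_sd * rng.standard_normal(n_vox)
    gm = np.clip((gm + noise) * gm_scale, 0.0, None)
    gm_map = ScalarMap(grid=grid, values=gm, name="gm")

    row = design.phenotype.iloc[index]
    voxel_vol = float(np.prod(grid.voxel_sizes_mm))
    pheno = dict(row)
    pheno["gmv"] = float(gm[brain].sum() * voxel_vol)
    return SubjectRecord(
        subject_id=str(row["subject_id"]), bold=bold, gm=gm_map, phenotype=pheno
    )


def iter_subjects(spec: SyntheticSpec) -> Iterator[SubjectRecord]:
    """Yield the cohort's subjects one at a time (constant memory)."""
    geometry = build_geometry(spec)
    design = cohort_metadata(spec)
    for i in range(spec.n_subjects):
        yield make_subject(spec, geometry, design, i)


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Materialize the full cohort in memory (use iter_subjects for large n)."""
    geometry = build_geometry(spec)
    design = cohort_metadata(spec)
    records = tuple(
        make_subject(spec, geometry, design, i) for i in range(spec.n_subjects)
    )
    return SyntheticCohort(spec=spec, geometry=geometry, design=design, records=records)


# ---------------------------------------------------------------------------
# On-disk study
# ---------------------------------------------------------------------------

def write_study(spec: SyntheticSpec, out_dir) -> Path:
    """Write a complete study (NIfTI volumes, phenotype TSV, ROI YAML,
    ground-truth JSON and a ready-to-run pipeline config) to ``out_dir``."""
    out = Path(out_dir)
    (out / "bold").mkdir(parents=True, exist_ok=True)
    (out / "gm").mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)

    geometry = build_geometry(spec)
    design = cohort_metadata(spec)
    grid = geometry.grid

    save_mask(grid.brain_mask, grid, out / "masks" / "brain.nii")
    save_mask(geometry.wm_mask, grid, out / "masks" / "wm.nii")
    save_mask(geometry.csf_mask, grid, out / "masks" / "csf.nii")

    rows = []
    for i in range(spec.n_subjects):
        rec = make_subject(spec, geometry, design, i)
        save_bold(rec.bold, out / "bold" / f"{rec.subject_id}_bold.nii")
        save_scalar(rec.gm, out / "gm" / f"{rec.subject_id}_gm.nii")
        rows.append(rec.phenotype)
    pd.DataFrame(rows).to_csv(out / "phenotype.tsv", sep="\t", index=False)

    roi_entries = [
        {"name": r.name, "set": r.system, "x": r.center_mm[0], "y": r.center_mm[1],
         "z": r.center_mm[2], "radius": r.radius_mm}
        for r in spec.regions
    ]
    (out / "rois.yaml").write_text(yaml.safe_dump(roi_entries, sort_keys=False))

    high, low = ground_truth_masks(geometry)
    truth = {
        "system_corr": spec.system_corr,
        "regions": {n: geometry.region_systems[n] for n in geometry.region_masks},
        "high_mask_voxels": int(high.sum()),
        "low_mask_voxels": int(low.sum()),
        "high_mask_indices": np.argwhere(high).tolist(),
        "low_mask_indices": np.argwhere(low).tolist(),
        "seed": spec.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, sort_keys=True))

    config = {
        "bold_dir": str(out / "bold"),
        "gm_dir": str(out / "gm"),
        "brain_mask": str(out / "masks" / "brain.nii"),
        "wm_mask": str(out / "masks" / "wm.nii"),
        "csf_mask": str(out / "masks" / "csf.nii"),
        "phenotype": str(out / "phenotype.tsv"),
        "roi_file": str(out / "rois.yaml"),
        "out_dir": str(out / "derivatives"),
        "band_hz": list(spec.band_hz),
        # planted spheres are only two voxels in radius and the generator has
        # no registration noise, so the synthetic study runs unsmoothed
        "fwhm_mm": 0.0,
        "tr_seconds": spec.tr_seconds,
    }
    (out / "study_config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return out
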