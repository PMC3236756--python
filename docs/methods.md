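# Methods

## The three estimators

**ALFF.** Each voxel's series (optionally smoothed, then linearly detrended
and ideal-band-pass filtered) is Fourier transformed; the per-bin amplitude
is the folded one-sided square-root power `2|X_k|/N`, so a pure sinusoid of
amplitude A on a single DFT bin yields exactly A. ALFF is the arithmetic
mean of these amplitudes over bins with `low ≤ k/(N·TR) ≤ high` (band edges
inclusive; DC always excluded; the unpaired Nyquist bin excluded). The
"mean of square-root power" order of operations — not the square root of the
mean power — is deliberate and pinned by oracle tests. Standardization
divides by the full-brain mean, making the in-mask mean exactly 1; because
the filter and the ALFF band coincide by default, filtering before ALFF is
nearly a no-op and both behaviours (filtered/unfiltered input) are
available.

**ALFF-FCN.** For seed ROI s, the per-subject mean standardized ALFF inside
the seed sphere is the regressor of a voxel-wise across-subject GLM with
mean-centered covariates (mean WM ALFF, mean CSF ALFF, center and sex as
drop-first dummy columns, age). The map is the t of the seed coefficient
(df = n − 2 − c), algebraically the partial-correlation t of
(voxel, seed | covariates); a brute-force residualize-then-correlate oracle
is enforced to max |Δt| < 1e-8 in the tests.

**TS-ICN.** Within each subject, the seed's mean band-passed series and
every voxel series are residualized against an intercept plus nuisance
columns (mean WM and CSF series, the global brain signal by default, and
optional motion parameters; constant columns are dropped with a log note).
The Pearson r of the residuals is carried to the group as Fisher
z = atanh(r) with |r| clipped at 1 − 1e-7 — z rather than the raw beta
because it is variance-stabilizing for the random-effects one-sample t that
follows (covariates: center, sex, age; the tested effect is the intercept,
so covariates are mean-centered). Residuals that are numerically constant
(norm below 1e-7 of the original series' centered norm) get z = 0 and a log
flag rather than noise-driven correlations.

**VBM-SCN.** The identical across-subject engine applied to (smoothed)
gray-matter volume maps, seeded with the ROI's mean GM volume; covariates
are total cranial volume, whole-GM volume, center, sex, age. When the
phenotype lacks `gmv` it is computed from the GM maps (voxel volume × sum).

## Thresholding and reporting

Family-wise error is controlled by **Bonferroni**: two-sided per-voxel level
α/V over the V in-mask voxels, t_crit the upper α/(2V) Student-t quantile at
the map's df. This is a deliberate, exactly testable choice instead of
random-field theory; it is conservative, so cluster extents are smaller than
an RFT-based pipeline would report. Voxels with zero residual variance are
flagged: t = 0 when the effect estimate is zero, ±1e8 (capped, logged)
otherwise, never NaN. Cluster tables are 26-connectivity connected
components of the positive and negative masks separately, reporting the peak
|t| voxel's world-mm coordinates, signed peak t and extent, sorted by extent
(peak |t| breaks ties); no anatomical labeling is attempted.

## Map-space analytics

Seed maps are compared by Pearson correlation of their t-fields over the
shared brain mask (not significance-restricted). The dissimilarity is
d = 1 − r by default, chosen so the conventional cut height 0.4 corresponds
to spatial r = 0.6; `sqrt(2(1−r))` and `(1−r)/2` are selectable because the
transform is a configuration choice, not something the method pins down.
Agglomeration is average linkage (UPGMA) by default with single/complete
selectable; the partition at a cut is monotone in the cut height (property-
tested).

Conjunctions count **sign-consistent** significances: a voxel enters the
positive (negative) conjunction mask only if it is FWE-significant with that
sign in at least k of the n maps; mixed signs never combine. Within a seed
set k = 2 of 3. Across the nine maps the sensory set's t-fields and masks
are sign-flipped *first*, then the k = 8 of 9 rule applies, so the positive
mask is the high-level (DMN+TPN) system and the negative mask the low-level
(sensory) system. The mean-t field is the mean of the unthresholded
t-fields, reported only inside the masks. The TS-ICN dichotomy negates the
DMN subject-level z-maps, averages them with the TPN maps per subject
(summing each side separately so identical inputs cancel exactly), and
applies the covariate-adjusted one-sample t plus FWE.

Dichotomy statistics: per-subject mean standardized ALFF inside each system
mask; Pearson r (with two-sided p) between the two subject vectors, and a
Welch two-sample t comparing their levels, plus mean ± SD per system.

## Synthetic cohorts

The generator's defaults are the shipped desk-scale study: a 24³ grid at
3 mm (brain = 33 mm-radius sphere, 5616 voxels), nine 6-mm spherical regions
— three per system (DMN, TPN, SN), laid out as non-overlapping analogues of
the canonical seeds — plus disjoint WM and CSF spheres, n = 60 subjects,
T = 150 at TR = 2 s. Temporal structure: every series is an equal-amplitude
random-phase sum of in-band DFT sinusoids (unit RMS, so region ALFF is
analytic in the amplitude), mixed as √ρ·module + √(1−ρ)·unique with
ρ = 0.5; the TPN module is the negated DMN module (planting the
within-subject anti-correlation) and SN is independent; white noise
sd 0.2 is added everywhere.

Across subjects, region amplitude is `1 + 0.12·f + covariate shift + ε`,
where f is the subject's high-level factor (DMN/TPN regions) or low-level
factor (SN regions), drawn bivariate normal with correlation −0.8, and
ε has sd 0.02. Covariate shifts (center offset 0.01, sex offset 0.01, age
slope 0.0005/yr) were budgeted a priori to stay an order of magnitude below
the system variance (common variance ≈ 2e-4 vs loading² = 0.0144), so the
planted −0.8 correlation survives into the measured dichotomy r
(attenuation ≈ 0.03–0.05) while remaining detectable — and removable — by
the covariate regression. Background voxels share the base amplitude 1.0,
which keeps the full-brain standardization denominator nearly constant
across subjects. GM maps load per-system structural factors (loading 0.1,
independent across systems: structural covariance shows no anti-correlated
partition) under a global scaling factor (sd 0.04) that the TCV/GMV
covariates absorb.

What the generator does **not** emulate: registration/segmentation error,
motion (regressors are emitted as zeros), physiological noise, scanner
drift beyond a linear trend, spatial autocorrelation of the noise, and
hemodynamic signal shapes. Passing tests therefore show the estimators and
analytics are correct and calibrated under the planted model, not that any
particular real-data effect size will replicate.

## Numerical choices and degenerate inputs

- Band-pass: ideal DFT mask on the detrended series (exactly invertible on
  retained bins; a Butterworth option is out of scope). Band-edge bins are
  included with a 1e-9 relative tolerance. DC is always removed.
- Smoothing: sampled-Gaussian kernel, σ = FWHM/(2√(2 ln 2)) per axis in mm
  converted to voxels; mask-aware renormalized convolution so brain-edge
  voxels are not diluted by out-of-mask zeros; FWHM 0 is the identity. The
  pipeline smooths before filtering. The synthetic study's config sets
  FWHM = 0: its planted spheres are only two voxels in radius and it has no
  registration noise, so the 8 mm default (appropriate at full MNI scale)
  would only blur the planted boundaries.
- Sphere membership: voxel-center distance ≤ radius (no partial volumes),
  with a 1e-9 mm tolerance; masks are intersected with the brain mask and an
  empty intersection is an error naming the ROI.
- Grids must agree in shape and affine to 1e-4 mm; volumes are written as
  uncompressed `.nii` (plus JSON provenance sidecars) so repeated runs are
  byte-identical; the manifest records SHA-256 checksums of every output.
- All operations treat inputs as immutable; every estimator is invariant to
  subject permutation and equivariant to seed sign flips (property-tested).

## Problem sizes

Unit and property tests run on flat toy grids (tens to hundreds of voxels).
End-to-end recovery checks use the generator at n = 300 subjects on the 24³
grid (streamed one subject at a time), null calibration uses 200 cohorts of
n = 30 × 500 voxels, and pipeline/determinism checks run 10–16 subjects —
the sizes at which each property is informative.

## Known limitations

- Bonferroni FWE is conservative relative to random-field or permutation
  approaches; permutation-based thresholds are a natural extension.
- The dissimilarity transform and linkage are configuration; dendrogram
  *heights* are therefore not comparable across configurations, only the
  partitions at a stated cut.
- No fALFF or frequency sub-bands; no ICA; no registration, slice timing,
  motion correction or segmentation — inputs must already share a space.
- Anatomical cluster labels are human annotations and out of scope.
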