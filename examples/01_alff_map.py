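"""Compute a standardized ALFF map for one synthetic subject.

ALFF (amplitude of low-frequency fluctuations) summarizes each voxel's
resting activity as the mean square-root spectral power in 0.01-0.08 Hz.
Planted network regions have subject-specific amplitudes, so their ALFF
stands apart from the background level of ~1 after full-brain
standardization.
"""

import numpy as np

from alffnet import compute_alff_map, standardize_alff
from alffnet.simulate import SyntheticSpec, build_geometry, cohort_metadata, make_subject

spec = SyntheticSpec(n_subjects=1, seed=1)
geometry = build_geometry(spec)
subject = make_subject(spec, geometry, cohort_metadata(spec), 0)

alff = standardize_alff(compute_alff_map(subject.bold, spec.band_hz))

print(f"subject {subject.subject_id}: grid {alff.grid.shape}, "
      f"band {alff.band_hz} Hz, TR {alff.tr_seconds} s")
print(f"in-brain mean ALFF (standardized): "
      f"{alff.values[geometry.grid.brain_mask].mean():.6f}")
print("mean standardized ALFF per planted region "
      "(region amplitude is subject-specific):")
for name, mask in geometry.region_masks.items():
    system = geometry.region_systems[name]
    print(f"  {name:6s} [{system}]  {alff.values[mask].mean():.3f}")
wm = alff.values[geometry.wm_mask].mean()
csf = alff.values[geometry.csf_mask].mean()
print(f"nuisance compartments: WM {wm:.3f}, CSF {csf:.3f} "
      "(used as covariates in the FCN model)")
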