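"""Run the complete study pipeline on a synthetic cohort and read the report.

Writes a study to disk (BOLD + GM NIfTI volumes, phenotype, ROI spec), runs
ALFF -> ICN/FCN/SCN -> clustering -> conjunctions -> dichotomy report via the
same code path as the `alffnet all` CLI command, then prints the clustering
partitions and the two-system dichotomy statistics.
"""

import json
import tempfile
from pathlib import Path

from alffnet import StudyConfig, run_study
from alffnet.simulate import SyntheticSpec, write_study

with tempfile.TemporaryDirectory() as td:
    # shipped desk-scale defaults: n=60 subjects, T=150, planted corr -0.8
    study = write_study(SyntheticSpec(seed=5), Path(td) / "study")
    config = StudyConfig.from_yaml(study / "study_config.yaml")
    manifest = run_study(config)
    out = Path(config.out_dir)

    print(f"pipeline wrote {len(manifest['files'])} files for "
          f"{manifest['n_subjects']} subjects")
    for est in ("fcn", "icn"):
        part = json.loads((out / "cluster" / f"{est}_partition.json").read_text())
        print(f"{est.upper()} partition at cut 0.4 -> {part['n_clusters']} clusters: "
              f"{part['partition']}")
    report = json.loads((out / "report" / "dichotomy.json").read_text())
    d = report["dichotomy"]
    if d is None:
        print("inter-set conjunction empty at this cohort size; "
              "no dichotomy statistics")
    else:
        print(f"two-system dichotomy: r = {d['r']:.3f} (p = {d['r_pvalue']:.2e}), "
              f"Welch t = {d['t_twosample']:.3f} (p = {d['t_pvalue']:.3f})")
        print(f"  high-level mean ALFF {d['high_mean']:.3f} +/- {d['high_sd']:.3f}, "
              f"low-level {d['low_mean']:.3f} +/- {d['low_sd']:.3f}")
    print("\nExpected at these settings: FCN clusters into 2 systems (DMN+TPN "
          "vs sensory) while ICN gives 3 modules, and the dichotomy r is "
          "strongly negative (planted across-subject correlation -0.8).")
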