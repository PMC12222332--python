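#!/usr/bin/env python
"""Fit FA maps for every scan and remove age and center effects.

Uses the direct FA sampling route at the full study size, fits per-center
age models on controls, applies the center-B gain/offset correction, and
verifies that no residual site effect survives a voxel-wise Welch/FDR
test. A spot check runs the DWI-simulation + log-linear tensor-fit route
on one subject to confirm both routes agree on the tube FA.
"""

import json
from pathlib import Path

import numpy as np

from tractfa import phantom, study
from tractfa.tensor import compute_fa, fit_tensor

OUT = Path("results/harmonize")
OUT.mkdir(parents=True, exist_ok=True)

spec = phantom.default_spec(seed=0)
cohort = phantom.assign_scores(spec, phantom.make_cohort(spec))
fa_maps = study.generate_fa_maps(spec, cohort)
corrected, report, _ = study.harmonize_fa_maps(spec, cohort, fa_maps)
with open(OUT / "site_effect_report.json", "w") as fh:
    json.dump(report, fh, indent=1)

print(f"harmonized {len(corrected)} scans")
print(f"residual site effect: {report['n_surviving']} / {report['n_voxels']} "
      f"voxels survive FDR (max mean residual "
      f"{report['max_abs_mean_residual']:.2e})")

# dual-route spot check: DWI simulation + tensor fit vs direct FA sampling
row = cohort[cohort.group == "control"].iloc[0]
gtab = phantom.protocol_gradient_table(31 if row["center"] == "A" else 65)
field = phantom.build_tensor_field(spec, row)
dwi = phantom.simulate_dwi(field, gtab, s0=spec.s0, noise_sd=spec.dwi_noise_sd,
                           rng=phantom.subject_rng(spec, row["subject_id"], 71))
fa_fit = compute_fa(fit_tensor(dwi, gtab, spec.affine))
tube = phantom.geometry(spec).tract_mask("cc_ii")
print(f"DWI-route tube FA {np.median(fa_fit.data[tube]):.3f} "
      f"(design 0.799) for subject {row['subject_id']}")
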