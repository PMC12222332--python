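#!/usr/bin/env python
"""Random-forest classification from TFAS and volumetry features.

Joins tract mean-FA features with ICV-standardized structure volumes,
runs stratified fivefold cross-validation with the fixed forest
hyperparameters (100 trees, Gini, depth 4, sqrt features, bootstrap),
and applies iterative Gini-importance feature elimination for the three
pairwise tasks.
"""

import json
from pathlib import Path

from tractfa import classify, phantom, study, volumetry

OUT = Path("results/classification")
OUT.mkdir(parents=True, exist_ok=True)

spec = phantom.default_spec(seed=0)
cohort = phantom.assign_scores(spec, phantom.make_cohort(spec))
fa_maps = study.generate_fa_maps(spec, cohort)
corrected, _, _ = study.harmonize_fa_maps(spec, cohort, fa_maps)
toi_masks = study.phantom_toi_masks(spec, seed=0)
records = study.tfas_from_masks(toi_masks, cohort, corrected)

base = cohort[cohort.timepoint == "baseline"]
atlas = phantom.build_atlas(spec)
maps = {r["subject_id"]: phantom.build_component_maps(spec, r)[:3]
        for _, r in base.iterrows()}
soi = volumetry.soi_table(maps, atlas, phantom.SOI_LABELS, cohort)

features = classify.assemble_features(records, soi, cohort)
summaries = {}
for task in (("nfppa", "control"), ("svppa", "control"), ("nfppa", "svppa")):
    final, trajectory = classify.gini_feature_elimination(features, task, seed=0)
    rep = next(r for r in reversed(trajectory) if r.features == final)
    summaries["_vs_".join(task)] = {**rep.summary(), "final_features": final}
    print(f"{task[0]} vs {task[1]}: accuracy {rep.accuracy:.2f} "
          f"+/- {rep.accuracy_sd:.2f}, sensitivity {rep.sensitivity:.2f}, "
          f"specificity {rep.specificity:.2f}; "
          f"top feature {rep.mean_importance().index[0]} "
          f"({len(final)} features kept)")
with open(OUT / "classification.json", "w") as fh:
    json.dump(summaries, fh, indent=1)
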