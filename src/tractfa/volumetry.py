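"""Atlas-based volumetry (ABV).

Structure volumes come from voxel-by-voxel multiplication of normalized,
modulated tissue-component maps with atlas label masks, integrated over the
label and expressed in ml. Volumes are linearly standardized to the control
group's mean intracranial volume (ICV = integrated GM+WM+CSF), and group
effects are summarized as z-scores against controls
(z = (group mean - control mean) / control SD) with Welch tests and
Benjamini–Hochberg correction across the structure family.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grids import ScalarMap


def integrate_soi(component: ScalarMap, atlas: ScalarMap,
                  soi_labels: dict[int, str]) -> dict[str, float]:
    """Integrated component volume per structure, in ml.

    volume = sum over labelled voxels of component value x voxel volume.
    """
    vv_ml = component.voxel_volume_mm3 / 1000.0
    labels = np.rint(atlas.data).astype(int)
    out = {}
    for lab, name in soi_labels.items():
        out[name] = float(component.data[labels == lab].sum() * vv_ml)
    return out


def compute_icv(gm: ScalarMap, wm: ScalarMap, csf: ScalarMap) -> float:
    """Intracranial volume in ml: integral of GM+WM+CSF probability."""
    vv_ml = gm.voxel_volume_mm3 / 1000.0
    return float((gm.data + wm.data + csf.data).sum() * vv_ml)


def standardize_icv(raw_ml: float, subject_icv_ml: float,
                    control_mean_icv_ml: float) -> float:
    """Linear head-size standardization: raw x control-mean-ICV / subject-ICV."""
    if subject_icv_ml <= 0:
        raise ValueError("subject ICV must be positive")
    return raw_ml * control_mean_icv_ml / subject_icv_ml


def soi_table(subject_maps: dict[str, tuple[ScalarMap, ScalarMap, ScalarMap]],
              atlas: ScalarMap, soi_labels: dict[int, str],
              cohort: pd.DataFrame,
              component: str = "gm") -> pd.DataFrame:
    """Tidy per-subject volumetry table.

    ``subject_maps`` maps subject_id -> (GM, WM, CSF). Columns: subject_id,
    soi, raw_volume_ml, icv_ml, standardized_volume_ml. The control mean
    ICV (baseline control subjects present in ``subject_maps``) is the
    standardization reference.
    """
    comp_idx = {"gm": 0, "wm": 1, "csf": 2}[component]
    icvs = {sid: compute_icv(*maps) for sid, maps in subject_maps.items()}
    base = cohort[cohort["timepoint"] == "baseline"] if "timepoint" in cohort else cohort
    control_ids = set(base.loc[base["group"] == "control", "subject_id"])
    ref_icvs = [v for sid, v in icvs.items() if sid in control_ids]
    if not ref_icvs:
        raise ValueError("no control subjects available to define the reference ICV")
    control_mean_icv = float(np.mean(ref_icvs))
    rows = []
    for sid, maps in subject_maps.items():
        vols = integrate_soi(maps[comp_idx], atlas, soi_labels)
        for name, raw in vols.items():
            rows.append(dict(subject_id=sid, soi=name, raw_volume_ml=raw,
                             icv_ml=icvs[sid],
                             standardized_volume_ml=standardize_icv(
                                 raw, icvs[sid], control_mean_icv)))
    return pd.DataFrame(rows)


def zscore_groups(table: pd.DataFrame, cohort: pd.DataFrame,
                  patient_groups: tuple[str, ...] = ("nfppa", "svppa"),
                  control_group: str = "control",
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per group x SOI: mean, SD, z vs controls, Welch q-values.

    Also tests the two patient groups against each other. BH correction is
    applied across SOIs within each contrast.
    """
    base = cohort[cohort["timepoint"] == "baseline"] if "timepoint" in cohort else cohort
    labels = base.set_index("subject_id")["group"]
    merged = table.join(labels, on="subject_id")
    rows = []
    for soi_name, sub in merged.groupby("soi", sort=True):
        ctl = sub.loc[sub["group"] == control_group, "standardized_volume_ml"].to_numpy()
        if len(ctl) < 2:
            raise ValueError("need >=2 controls per SOI")
        c_mean, c_sd = ctl.mean(), ctl.std(ddof=1)
        for g in (control_group,) + tuple(patient_groups):
            vals = sub.loc[sub["group"] == g, "standardized_volume_ml"].to_numpy()
            if len(vals) == 0:
                continue
            z = (vals.mean() - c_mean) / c_sd if c_sd > 0 else 0.0
            if g == control_group:
                p = 1.0
            else:
                _, p = stats.ttest_ind(vals, ctl, equal_var=False)
            rows.append(dict(soi=soi_name, group=g, mean_ml=vals.mean(),
                             sd_ml=vals.std(ddof=1) if len(vals) > 1 else 0.0,
                             z=float(z), contrast=f"{g}_vs_{control_group}",
                             p=float(p)))
        if len(patient_groups) == 2:
            a = sub.loc[sub["group"] == patient_groups[0], "standardized_volume_ml"].to_numpy()
            b = sub.loc[sub["group"] == patient_groups[1], "standardized_volume_ml"].to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                _, p = stats.ttest_ind(a, b, equal_var=False)
                rows.append(dict(soi=soi_name, group=patient_groups[0],
                                 mean_ml=a.mean(), sd_ml=a.std(ddof=1),
                                 z=float((a.mean() - c_mean) / c_sd if c_sd > 0 else 0.0),
                                 contrast=f"{patient_groups[0]}_vs_{patient_groups[1]}",
                                 p=float(p)))
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["significant"] = False
    for contrast, idx in out.groupby("contrast").groups.items():
        if contrast == f"{control_group}_vs_{control_group}":
            continue  # controls against themselves: z = 0 by construction
        idx = list(idx)
        rej, q, _, _ = multipletests(out.loc[idx, "p"].to_numpy(),
                                     alpha=alpha, method="fdr_bh")
        out.loc[idx, "q"] = q
        out.loc[idx, "significant"] = rej
    return out


def longitudinal_volumes(table_t0: pd.DataFrame, table_t1: pd.DataFrame,
                         cohort: pd.DataFrame,
                         control_group: str = "control",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Baseline-vs-follow-up change per SOI within patients.

    Paired t-test on standardized volumes for subjects present at both
    timepoints, plus z-scores at each timepoint against baseline controls;
    BH correction across SOIs.
    """
    base = cohort[cohort["timepoint"] == "baseline"] if "timepoint" in cohort else cohort
    labels = base.set_index("subject_id")["group"]
    ctl_ids = set(labels[labels == control_group].index)
    rows = []
    for soi_name in sorted(table_t0["soi"].unique()):
        s0 = table_t0[table_t0["soi"] == soi_name].set_index("subject_id")
        s1 = table_t1[table_t1["soi"] == soi_name].set_index("subject_id")
        common = [sid for sid in s1.index if sid in s0.index and sid not in ctl_ids]
        if len(common) < 2:
            raise ValueError(f"SOI {soi_name}: paired test needs >=2 subjects "
                             f"with both timepoints")
        v0 = s0.loc[common, "standardized_volume_ml"].to_numpy()
        v1 = s1.loc[common, "standardized_volume_ml"].to_numpy()
        if np.allclose(v0, v1):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(v1, v0)
        ctl = s0.loc[[i for i in s0.index if i in ctl_ids], "standardized_volume_ml"]
        c_mean, c_sd = ctl.mean(), ctl.std(ddof=1)
        z0 = (v0.mean() - c_mean) / c_sd if c_sd > 0 else 0.0
        z1 = (v1.mean() - c_mean) / c_sd if c_sd > 0 else 0.0
        rows.append(dict(soi=soi_name, n_pairs=len(common),
                         mean_t0=v0.mean(), mean_t1=v1.mean(),
                         delta=v1.mean() - v0.mean(), t=float(t), p=float(p),
                         z_t0=float(z0), z_t1=float(z1),
                         delta_z=float(z1 - z0)))
    out = pd.DataFrame(rows)
    rej, q, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = rej
    return out
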