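"""Standard study workflows built from the pipeline stages.

These helpers bundle the stage sequence the analyses share — sample FA
maps, remove age and center effects with control-derived models, smooth,
run the voxel statistics — into single calls used by the analysis scripts,
the test suite, and the acceptance checks. Each run helper is driven by an
explicit seed and returns plain numbers, so replicated runs are cheap and
reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import harmonize as harm
from . import phantom, tracking, wbss
from .grids import ScalarMap
from .phantom import BASELINE, FOLLOWUP, PhantomSpec
from .register import smooth
from .tensor import compute_fa


def desk_groups(n_per_group: int = 25):
    """Equal-size desk-scale groups with the study's age structure."""
    return [("control", n_per_group, 57.9, 11.6),
            ("nfppa", n_per_group, 60.4, 5.0),
            ("svppa", n_per_group, 62.4, 10.4)]


# Monte-Carlo recovery conditions use a center-balanced cohort: with equal
# center composition across groups, the sampling error of the control-based
# center correction is common mode between patients and controls and cancels
# from the group contrasts, so these conditions measure lesion/correlation
# recovery rather than composition-coupled harmonization noise.
BALANCED_CENTERS = {"control": 0.5, "nfppa": 0.5, "svppa": 0.5}


def generate_fa_maps(spec: PhantomSpec, cohort: pd.DataFrame,
                     rng: np.random.Generator | None = None
                     ) -> dict[tuple[str, str], ScalarMap]:
    """Observed FA map per (subject, timepoint) via the direct sampling route."""
    maps = {}
    for _, row in cohort.iterrows():
        key = (row["subject_id"], row["timepoint"])
        sub_rng = None if rng is None else rng
        maps[key] = phantom.sample_fa_map(spec, row, row["timepoint"], rng=sub_rng)
    return maps


def harmonize_fa_maps(spec: PhantomSpec, cohort: pd.DataFrame,
                      fa_maps: dict[tuple[str, str], ScalarMap],
                      mode: str = "gain_offset"):
    """Age correction (per-center control OLS) then center correction (B -> A).

    Returns (corrected maps, site-effect verification report, center model).
    """
    base = cohort[cohort["timepoint"] == BASELINE]
    models = {}
    for center in ("A", "B"):
        ctl = base[(base.group == "control") & (base.center == center)]
        maps = [fa_maps[(r.subject_id, BASELINE)] for r in ctl.itertuples()]
        models[center] = harm.fit_age_model(
            maps, ctl["age"].to_numpy(), reference_age=spec.reference_age,
            center=center)
    age_corr = {}
    for _, row in cohort.iterrows():
        key = (row["subject_id"], row["timepoint"])
        age_corr[key] = harm.apply_age_correction(
            fa_maps[key], row["age"], models[row["center"]])

    ctl_a = base[(base.group == "control") & (base.center == "A")]
    ctl_b = base[(base.group == "control") & (base.center == "B")]
    cc = harm.fit_center_correction(
        [age_corr[(r.subject_id, BASELINE)] for r in ctl_a.itertuples()],
        [age_corr[(r.subject_id, BASELINE)] for r in ctl_b.itertuples()],
        mode=mode)
    corrected = {}
    for _, row in cohort.iterrows():
        key = (row["subject_id"], row["timepoint"])
        corrected[key] = cc.apply(age_corr[key]) if row["center"] == "B" \
            else age_corr[key]
    ctl_corr = [corrected[(r.subject_id, BASELINE)]
                for r in pd.concat([ctl_a, ctl_b]).itertuples()]
    verify_mask = wbss.analysis_mask(ctl_corr)
    report = harm.verify_no_site_effect(
        [corrected[(r.subject_id, BASELINE)] for r in ctl_a.itertuples()],
        [corrected[(r.subject_id, BASELINE)] for r in ctl_b.itertuples()],
        mask=verify_mask)
    return corrected, report, cc


def smoothed_group_maps(cohort: pd.DataFrame,
                        corrected: dict[tuple[str, str], ScalarMap],
                        fwhm_mm: float = 8.0,
                        fa_threshold: float = 0.2):
    """Analysis mask from unsmoothed corrected maps + mask-renormalized smoothing."""
    base = cohort[cohort["timepoint"] == BASELINE]
    all_maps = [corrected[(r.subject_id, BASELINE)] for r in base.itertuples()]
    mask = wbss.analysis_mask(all_maps, fa_threshold)
    smoothed = {k: smooth(v, fwhm_mm, mask=mask) for k, v in corrected.items()}
    return mask, smoothed


def group_maps(cohort: pd.DataFrame, maps: dict, group: str,
               timepoint: str = BASELINE) -> list[ScalarMap]:
    sel = cohort[(cohort.group == group) & (cohort.timepoint == timepoint)]
    return [maps[(r.subject_id, timepoint)] for r in sel.itertuples()]


def phantom_toi_masks(spec: PhantomSpec, seed: int = 0,
                      params: tracking.TrackingParams | None = None
                      ) -> dict[str, np.ndarray]:
    """Tract masks from seed-to-target tracking on the control template.

    The template is built from noiseless control tensor fields (identical
    across controls by construction, so a small number suffices).
    """
    cohort = phantom.make_cohort(spec)
    ctl = cohort[(cohort.group == "control")
                 & (cohort.timepoint == BASELINE)].head(2)
    fields = [phantom.build_tensor_field(spec, r, BASELINE)
              for _, r in ctl.iterrows()]
    template = tracking.average_tensor_template(fields)
    fa_template = compute_fa(template)
    tois = tracking.phantom_toi_definitions(spec, fa_template)
    out = {}
    for toi in tois:
        res = tracking.track(template, toi, params, seed=seed)
        out[toi.name] = res.tract_mask()
    return out


def tfas_from_masks(toi_masks: dict[str, np.ndarray],
                    cohort: pd.DataFrame, corrected: dict,
                    timepoint: str = BASELINE) -> pd.DataFrame:
    """TFAS table using precomputed tract masks (voxel-level definition)."""
    rows = []
    sel = cohort[cohort["timepoint"] == timepoint]
    for r in sel.itertuples():
        fa = corrected[(r.subject_id, timepoint)].data
        for name, m in toi_masks.items():
            use = m & (fa > tracking.FA_TRACK_THRESHOLD)
            n = int(use.sum())
            rows.append(dict(subject_id=r.subject_id, toi=name,
                             mean_fa=float(fa[use].mean()) if n else np.nan,
                             n_voxels=n))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# replicated-run helpers (Monte-Carlo study conditions)
# --------------------------------------------------------------------------

def lesion_recovery_run(seed: int, n_per_group: int = 25,
                        toi_masks: dict[str, np.ndarray] | None = None,
                        spec: PhantomSpec | None = None) -> dict:
    """One replicate of the cross-sectional analysis on a fresh cohort.

    Runs harmonization, WBSS (8 mm smoothing, BH FDR 0.05, 256-voxel
    clusters) and TFAS for both patient groups; reports the Dice overlap of
    the surviving-cluster mask with the planted lesion and the TFAS
    detection pattern.
    """
    groups = desk_groups(n_per_group) if spec is None else spec.groups
    spec = phantom.default_spec(seed=seed, groups=groups, followup_groups={},
                                center_a_fraction=dict(BALANCED_CENTERS))
    cohort = phantom.assign_scores(spec, phantom.make_cohort(spec))
    fa_maps = generate_fa_maps(spec, cohort)
    corrected, site_report, _ = harmonize_fa_maps(spec, cohort, fa_maps)
    mask, smoothed = smoothed_group_maps(cohort, corrected)
    geom = phantom.geometry(spec)

    out = {"site_report": site_report}
    lesion_by_group = {g: les for les in spec.lesions for g in les.affected_groups}
    for grp, les in lesion_by_group.items():
        pat = group_maps(cohort, smoothed, grp)
        ctl = group_maps(cohort, smoothed, "control")
        rep = wbss.group_compare(pat, ctl, mask)
        truth = geom.lesion_mask(les)
        surv = rep.surviving
        dice = 2 * (surv & truth).sum() / max(surv.sum() + truth.sum(), 1)
        out[grp] = {"dice": float(dice), "n_clusters": len(rep.clusters),
                    "surviving_voxels": int(surv.sum())}
    if toi_masks is not None:
        records = tfas_from_masks(toi_masks, cohort, corrected)
        for grp, les in lesion_by_group.items():
            tests = tracking.tfas_group_test(records, cohort, grp, "control")
            sig = set(tests.loc[tests.significant, "toi"])
            out[grp]["tfas_hit"] = les.tract_name in sig
            out[grp]["tfas_false"] = sorted(sig - {les.tract_name})
    return out


def correlation_recovery_run(seed: int, n_patients: int = 29,
                             group: str = "nfppa") -> dict:
    """One replicate of the FA ~ FTLD-CDR correlation analysis.

    Returns the Pearson R at the peak of the largest surviving cluster (nan
    when nothing survives) and the designed lesion-group size.
    """
    groups = [("control", 25, 57.9, 11.6), (group, n_patients, 60.4, 5.0)]
    spec = phantom.default_spec(seed=seed, groups=groups, followup_groups={},
                                center_a_fraction=dict(BALANCED_CENTERS))
    cohort = phantom.assign_scores(spec, phantom.make_cohort(spec))
    fa_maps = generate_fa_maps(spec, cohort)
    corrected, _, _ = harmonize_fa_maps(spec, cohort, fa_maps)
    mask, smoothed = smoothed_group_maps(cohort, corrected)
    base = cohort[cohort["timepoint"] == BASELINE]
    pat = base[base.group == group]
    maps = [smoothed[(r.subject_id, BASELINE)] for r in pat.itertuples()]
    rep = wbss.correlation_map(maps, pat["ftld_cdr_sob"].to_numpy(), mask)
    peak_r = rep.clusters[0].peak_r if rep.clusters else float("nan")
    return {"peak_r": float(peak_r) if peak_r is not None else float("nan"),
            "n_clusters": len(rep.clusters)}


def longitudinal_growth_run(seed: int, n_patients: int = 10,
                            n_controls: int = 25) -> dict:
    """One replicate of the longitudinal WBSS contrast.

    The same patients are analysed at baseline and at follow-up (deeper,
    longer lesion) against the same baseline controls; reports whether the
    matched main cluster grew.
    """
    groups = [("control", n_controls, 57.9, 11.6), ("nfppa", n_patients, 60.4, 5.0)]
    spec = phantom.default_spec(seed=seed, groups=groups,
                                followup_groups={"nfppa": n_patients},
                                center_a_fraction=dict(BALANCED_CENTERS))
    cohort = phantom.assign_scores(spec, phantom.make_cohort(spec))
    fa_maps = generate_fa_maps(spec, cohort)
    corrected, _, _ = harmonize_fa_maps(spec, cohort, fa_maps)
    mask, smoothed = smoothed_group_maps(cohort, corrected)
    fu = cohort[(cohort.timepoint == FOLLOWUP) & (cohort.group == "nfppa")]
    ids = fu["subject_id"].tolist()
    t0 = [smoothed[(sid, BASELINE)] for sid in ids]
    t1 = [smoothed[(sid, FOLLOWUP)] for sid in ids]
    ctl = group_maps(cohort, smoothed, "control")
    rep0, rep1, growth = wbss.longitudinal_compare(t0, t1, ctl, mask)
    if len(growth) == 0:
        return {"grew": False, "growth": 0, "size_t0": 0, "size_t1": 0}
    main = growth.sort_values("size_t0", ascending=False).iloc[0]
    return {"grew": bool(main["size_t1"] > main["size_t0"]),
            "growth": int(main["growth"]),
            "size_t0": int(main["size_t0"]), "size_t1": int(main["size_t1"])}


def _feature_matrix(X: np.ndarray, labels: list[str], prefix: str = "toi_f"):
    from .classify import FeatureMatrix
    cols = [f"{prefix}{j}" for j in range(X.shape[1])]
    idx = [f"s{i:03d}" for i in range(X.shape[0])]
    return FeatureMatrix(pd.DataFrame(X, index=idx, columns=cols),
                         pd.Series(labels, index=idx, name="group"))


def classifier_null_run(seed: int, n_per_class: int = 30,
                        n_features: int = 10, permute: bool = False) -> float:
    """CV accuracy when both classes are draws from one distribution.

    ``permute=True`` additionally shuffles the labels (the same null)."""
    from .classify import cv_train
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    labels = ["a"] * n_per_class + ["b"] * n_per_class
    if permute:
        labels = list(rng.permutation(labels))
    fm = _feature_matrix(X, labels)
    return cv_train(fm, ("a", "b"), seed=seed).accuracy


def classifier_separable_run(seed: int, n_per_class: int = 30,
                             n_features: int = 10,
                             separation_sd: float = 10.0):
    """CV report for two classes split by ``separation_sd`` on feature 0."""
    from .classify import cv_train
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    X[:n_per_class, 0] += separation_sd
    labels = ["a"] * n_per_class + ["b"] * n_per_class
    fm = _feature_matrix(X, labels)
    return cv_train(fm, ("a", "b"), seed=seed)


def elimination_run(seed: int, n_per_class: int = 30, n_noise: int = 9,
                    effect_sd: float = 3.0) -> bool:
    """Does Gini elimination retain the single informative feature?"""
    from .classify import gini_feature_elimination
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, 1 + n_noise))
    X[:n_per_class, 0] += effect_sd
    labels = ["a"] * n_per_class + ["b"] * n_per_class
    fm = _feature_matrix(X, labels)
    final, _ = gini_feature_elimination(fm, ("a", "b"), seed=seed)
    return "toi_f0" in final


def fdp_run(seed: int, shape=(24, 24, 24), n_per_group: int = 15,
            signal_fraction: float = 0.1, effect: float = 1.0,
            noise_sigma_vox: float = 1.5, alpha: float = 0.05) -> float:
    """Realized false-discovery proportion of one BH run on a smooth-noise
    mixture phantom (90% null voxels, 10% strong-signal voxels)."""
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(shape))
    n_sig = int(round(signal_fraction * n_vox))
    sig_idx = rng.choice(n_vox, size=n_sig, replace=False)
    signal = np.zeros(n_vox)
    signal[sig_idx] = effect
    signal = signal.reshape(shape)
    from scipy.ndimage import gaussian_filter
    aff = np.eye(4)

    def draw(n, add_signal):
        out = []
        for _ in range(n):
            noise = gaussian_filter(rng.normal(size=shape), noise_sigma_vox)
            noise /= noise.std()
            out.append(ScalarMap(noise + (signal if add_signal else 0.0), aff))
        return out

    a = draw(n_per_group, True)
    b = draw(n_per_group, False)
    mask = np.ones(shape, dtype=bool)
    _, p_map, _ = wbss.welch_map(a, b, mask)
    _, rej = wbss.fdr_correct(p_map, mask, alpha)
    n_rej = rej.sum()
    if n_rej == 0:
        return 0.0
    truth = signal > 0
    fp = (rej & ~truth).sum()
    return float(fp / n_rej)
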