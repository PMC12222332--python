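"""Seed-to-target streamline tracking on a group tensor template, and
tract-wise FA statistics (TFAS).

Tracts of interest (TOIs) are defined on an averaged control tensor
template: streamlines are launched from every seed-region voxel, stepped
along the local principal diffusion direction, and only those that reach
the target region are retained; their voxel visitation map defines the
TOI. The tracker is a modified streamline scheme: before the eigenvector
is extracted, the trilinearly interpolated tensor is averaged with its six
grid neighbours, so the step direction carries the directional information
of neighbouring fibre tissue; a bounded random angular perturbation makes
the scheme probabilistic. Voxels at FA <= 0.2 are never entered.

TFAS then averages each subject's FA over the visited voxels (subject FA
above the 0.2 threshold), one scalar per subject and tract, and group
contrasts on these means use Welch tests with Benjamini–Hochberg
correction across the tract family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grids import ScalarMap, TensorField
from .tensor import compute_fa

FA_TRACK_THRESHOLD = 0.2

# The study's tract-of-interest catalogue; synthetic phantoms map a subset
# of these names onto their tubes.
TOI_CATALOG = [
    "left_uncinate_fasciculus", "right_uncinate_fasciculus",
    "cc_genu", "cc_ii", "cc_iii", "cc_iv", "cc_splenium",
    "left_slf", "right_slf", "left_ilf", "right_ilf",
    "ifof", "cingulum", "pontine_projections",
    "anterior_thalamic_radiation", "corticostriatal_projections",
    "corticospinal_tract", "optic_radiation", "fornix",
    "left_tapetum", "right_tapetum",
]


@dataclass
class TrackingParams:
    step_mm: float = 1.0
    max_angle_deg: float = 45.0
    n_seeds_per_voxel: int = 5
    perturbation_deg: float = 10.0
    max_length_mm: float = 200.0
    fa_threshold: float = FA_TRACK_THRESHOLD


@dataclass
class TOIDefinition:
    name: str
    seed_mask: np.ndarray
    target_mask: np.ndarray

    def __post_init__(self) -> None:
        self.seed_mask = np.asarray(self.seed_mask, dtype=bool)
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        if not self.seed_mask.any() or not self.target_mask.any():
            raise ValueError(f"TOI {self.name}: seed and target must be non-empty")
        if (self.seed_mask & self.target_mask).any():
            raise ValueError(f"TOI {self.name}: seed and target overlap")


@dataclass
class TOIResult:
    toi: TOIDefinition
    streamlines: list[np.ndarray]          # world-mm polylines
    visitation: ScalarMap                  # streamline count per voxel
    n_launched: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.streamlines)

    def tract_mask(self) -> np.ndarray:
        return self.visitation.data >= 1


@dataclass
class TFASRecord:
    subject_id: str
    toi: str
    mean_fa: float
    n_voxels: int


def sphere_mask(reference: ScalarMap, center_mm, radius_mm: float) -> np.ndarray:
    """Voxel ball: all voxels whose world centre lies within radius of center."""
    shape = reference.shape
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = reference.voxel_to_world(vox)
    d = np.linalg.norm(world - np.asarray(center_mm, dtype=float), axis=1)
    return (d <= radius_mm + 1e-9).reshape(shape)


def average_tensor_template(control_fields: list[TensorField]) -> TensorField:
    """Component-wise arithmetic mean of aligned control tensor fields.

    Only controls should be averaged, to keep the template free of
    pathology-driven bias; the caller owns that selection.
    """
    if not control_fields:
        raise ValueError("need at least one control field")
    ref = control_fields[0]
    mean = np.mean(np.stack([f.data for f in control_fields]), axis=0)
    return TensorField(mean, ref.affine.copy())


def _neighborhood_averaged(field: TensorField) -> np.ndarray:
    """Tensor components averaged with the 6-neighbourhood (edge-padded)."""
    d = field.data
    out = d.copy()
    for axis in range(3):
        out += np.concatenate([d.take([0], axis=axis), d], axis=axis).take(
            range(d.shape[axis]), axis=axis)
        out += np.concatenate([d, d.take([-1], axis=axis)], axis=axis).take(
            range(1, d.shape[axis] + 1), axis=axis)
    return out / 7.0


def _trilinear(arr: np.ndarray, p: np.ndarray):
    """Trilinear sample of a (X,Y,Z,C) array at voxel-space point p."""
    i0 = np.floor(p).astype(int)
    shape = arr.shape[:3]
    if np.any(i0 < 0) or np.any(i0 + 1 >= shape):
        return None
    f = p - i0
    c00 = arr[i0[0], i0[1], i0[2]] * (1 - f[2]) + arr[i0[0], i0[1], i0[2] + 1] * f[2]
    c01 = arr[i0[0], i0[1] + 1, i0[2]] * (1 - f[2]) + arr[i0[0], i0[1] + 1, i0[2] + 1] * f[2]
    c10 = arr[i0[0] + 1, i0[1], i0[2]] * (1 - f[2]) + arr[i0[0] + 1, i0[1], i0[2] + 1] * f[2]
    c11 = arr[i0[0] + 1, i0[1] + 1, i0[2]] * (1 - f[2]) + arr[i0[0] + 1, i0[1] + 1, i0[2] + 1] * f[2]
    c0 = c00 * (1 - f[1]) + c01 * f[1]
    c1 = c10 * (1 - f[1]) + c11 * f[1]
    return c0 * (1 - f[0]) + c1 * f[0]


def _principal_direction(comp6: np.ndarray) -> np.ndarray:
    D = np.array([[comp6[0], comp6[1], comp6[2]],
                  [comp6[1], comp6[3], comp6[4]],
                  [comp6[2], comp6[4], comp6[5]]])
    w, v = np.linalg.eigh(D)
    return v[:, 2]


def _perturb(direction: np.ndarray, max_deg: float,
             rng: np.random.Generator) -> np.ndarray:
    """Rotate by a uniform angle in [0, max_deg] about a random axis."""
    if max_deg <= 0:
        return direction
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    ref = rng.normal(size=3)
    axis = np.cross(direction, ref)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        return direction
    axis /= norm
    c, s = np.cos(angle), np.sin(angle)
    return (direction * c + np.cross(axis, direction) * s)


def track(template: TensorField, toi: TOIDefinition,
          params: TrackingParams | None = None,
          seed: int = 0) -> TOIResult:
    """Launch streamlines from every seed voxel; keep those reaching the target.

    Returns an (possibly empty) TOIResult; an unconnected seed/target pair is
    a legitimate empty outcome, not an error.
    """
    params = params or TrackingParams()
    rng = np.random.default_rng(seed)
    fa = compute_fa(template).data
    avg = _neighborhood_averaged(template)
    inv_aff = np.linalg.inv(template.affine)
    A, t = template.affine[:3, :3], template.affine[:3, 3]
    Ainv, tinv = inv_aff[:3, :3], inv_aff[:3, 3]
    cos_max = np.cos(np.deg2rad(params.max_angle_deg))
    shape = template.shape

    def to_vox(pw):
        return Ainv @ pw + tinv

    def in_mask(mask, pw):
        v = np.rint(to_vox(pw)).astype(int)
        if np.any(v < 0) or np.any(v >= shape):
            return False
        return bool(mask[tuple(v)])

    seeds = np.argwhere(toi.seed_mask)
    streamlines: list[np.ndarray] = []
    visitation = np.zeros(shape, dtype=np.int64)
    n_launched = 0

    for sv in seeds:
        if fa[tuple(sv)] <= params.fa_threshold:
            continue
        for _ in range(params.n_seeds_per_voxel):
            jitter = rng.uniform(-0.5, 0.5, size=3)
            start_vox = sv + jitter
            start_w = A @ start_vox + t
            d6 = _trilinear(avg, start_vox)
            if d6 is None:
                continue
            e1 = _principal_direction(d6)
            n_launched += 1
            # try both polarities; a launch is retained once it reaches the target
            for polarity in (1.0, -1.0):
                pts = _integrate(start_w, polarity * e1, avg, fa, toi.target_mask,
                                 params, rng, to_vox, in_mask, shape, cos_max)
                if pts is not None:
                    streamlines.append(pts)
                    vox = np.unique(np.clip(np.rint(
                        (pts @ Ainv.T) + tinv).astype(int), 0,
                        np.array(shape) - 1), axis=0)
                    visitation[tuple(vox.T)] += 1
                    break

    vis = ScalarMap(visitation.astype(float), template.affine.copy(), "mask")
    return TOIResult(toi, streamlines, vis, n_launched)


def _integrate(start_w, direction, avg, fa, target_mask, params, rng,
               to_vox, in_mask, shape, cos_max):
    """Step a single streamline; return its points if it reaches the target."""
    step = params.step_mm
    max_steps = int(params.max_length_mm / step)
    p = np.array(start_w, dtype=float)
    d_prev = np.array(direction, dtype=float)
    d_prev /= np.linalg.norm(d_prev)
    pts = [p.copy()]
    for _ in range(max_steps):
        vox = to_vox(p)
        d6 = _trilinear(avg, vox)
        if d6 is None:
            return None                      # left the grid
        e1 = _principal_direction(d6)
        if np.dot(e1, d_prev) < 0:           # sign-align to the previous step
            e1 = -e1
        e1 = _perturb(e1, params.perturbation_deg, rng)
        e1 /= np.linalg.norm(e1)
        if np.dot(e1, d_prev) < cos_max:
            return None                      # turned too sharply
        p_new = p + step * e1
        vox_new = to_vox(p_new)
        i_new = np.rint(vox_new).astype(int)
        if np.any(i_new < 0) or np.any(i_new >= shape):
            return None
        if fa[tuple(i_new)] <= params.fa_threshold:
            return None                      # entered low-anisotropy tissue
        pts.append(p_new.copy())
        if in_mask(target_mask, p_new):
            return np.asarray(pts)           # terminated in the target
        p = p_new
        d_prev = e1
    return None                              # exceeded max length


def tfas(toi_result: TOIResult, subject_fa: ScalarMap,
         fa_threshold: float = FA_TRACK_THRESHOLD,
         subject_id: str = "") -> TFASRecord:
    """Arithmetic mean of subject FA over the tract's visited voxels.

    Voxels where the subject's FA is at or below the threshold are omitted,
    mirroring the tracking criterion. Defined at the voxel level, so the
    result is invariant to streamline order and duplication.
    """
    sel = toi_result.tract_mask() & (subject_fa.data > fa_threshold)
    n = int(sel.sum())
    mean_fa = float(subject_fa.data[sel].mean()) if n else float("nan")
    return TFASRecord(subject_id, toi_result.toi.name, mean_fa, n)


def tfas_table(toi_results: dict[str, TOIResult],
               subject_fa_maps: dict[str, ScalarMap]) -> pd.DataFrame:
    """TFAS records for every subject x TOI, as a tidy table."""
    rows = []
    for sid, fa_map in subject_fa_maps.items():
        for name, res in toi_results.items():
            rec = tfas(res, fa_map, subject_id=sid)
            rows.append(dict(subject_id=sid, toi=name,
                             mean_fa=rec.mean_fa, n_voxels=rec.n_voxels))
    return pd.DataFrame(rows)


def tfas_group_test(records: pd.DataFrame, cohort: pd.DataFrame,
                    group_a: str, group_b: str,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Welch test per TOI between two groups, BH-corrected across TOIs.

    ``records`` is a tidy table (subject_id, toi, mean_fa); the cohort table
    supplies group labels (baseline rows).
    """
    base = cohort[cohort["timepoint"] == "baseline"] if "timepoint" in cohort else cohort
    labels = base.set_index("subject_id")["group"]
    merged = records.join(labels, on="subject_id")
    rows = []
    for toi_name, sub in merged.groupby("toi", sort=True):
        a = sub.loc[sub["group"] == group_a, "mean_fa"].dropna().to_numpy()
        b = sub.loc[sub["group"] == group_b, "mean_fa"].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"TOI {toi_name}: need >=2 subjects per group for Welch test")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(dict(toi=toi_name, mean_a=a.mean(), mean_b=b.mean(),
                         t=float(t), p=float(p),
                         direction="decrease" if a.mean() < b.mean() else "increase"))
    out = pd.DataFrame(rows)
    rej, q, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = rej
    return out


def phantom_toi_definitions(spec, fa_template: ScalarMap,
                            inset_mm: float = 6.0,
                            radius_mm: float = 6.0) -> list[TOIDefinition]:
    """Seed/target sphere pairs at the ends of each phantom tube."""
    tois = []
    for tract in spec.tracts:
        line = tract.centerline
        seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        p_seed = _point_at(line, cum, inset_mm)
        p_target = _point_at(line, cum, total - inset_mm)
        seed = sphere_mask(fa_template, p_seed, radius_mm)
        target = sphere_mask(fa_template, p_target, radius_mm)
        target &= ~seed
        tois.append(TOIDefinition(tract.name, seed, target))
    return tois


def _point_at(line, cum, s):
    j = int(np.clip(np.searchsorted(cum, s) - 1, 0, len(cum) - 2))
    seg = line[j + 1] - line[j]
    L = cum[j + 1] - cum[j]
    frac = (s - cum[j]) / L if L > 0 else 0.0
    return line[j] + frac * seg
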