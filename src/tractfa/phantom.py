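"""Synthetic two-center DTI cohort generator with known ground truth.

The phantom emulates the ingredients a multiparametric white-matter study
rests on, at desk scale: a small 3-D grid holding a few cylindrical
"tracts" of anisotropic diffusion in an isotropic background, three
diagnostic groups (controls and two patient variants), lesions planted on
specific tracts as FA reductions, an additive center effect and a linear
age effect on FA, ~12-month follow-up scans with lesion progression,
atlas-labelled tissue-probability maps with group-specific atrophy, and a
clinical severity score (FTLD-CDR sum of boxes) coupled to lesion depth.

Every random draw is keyed on the phantom seed and the subject id, so
identical specs produce bit-identical cohorts. A truth structure (lesion
masks, per-subject lesion depth, atrophy factors) is emitted for test
consumption only; no analysis stage reads it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import ScalarMap, TensorField, default_affine
from .tensor import fa_from_eigenvalues

BASELINE = "baseline"
FOLLOWUP = "followup"


# --------------------------------------------------------------------------
# specification dataclasses
# --------------------------------------------------------------------------

@dataclass
class TractGeometry:
    """A cylindrical tract: polyline centreline (world mm) + radius + diffusivities."""

    name: str
    centerline: np.ndarray        # (N, 3) world mm
    radius: float                 # mm
    lambda_parallel: float = 1.7e-3   # mm^2/s
    lambda_perp: float = 0.3e-3       # mm^2/s

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if self.radius <= 0:
            raise ValueError(f"tract {self.name}: radius must be positive")
        if not (self.lambda_parallel > self.lambda_perp > 0):
            raise ValueError(f"tract {self.name}: need lambda_parallel > lambda_perp > 0")

    @property
    def fa(self) -> float:
        return float(fa_from_eigenvalues(
            np.array([self.lambda_parallel, self.lambda_perp, self.lambda_perp])))

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)))


@dataclass
class LesionSpec:
    """FA reduction over an arc-length span of one tract, for given groups."""

    tract_name: str
    span: tuple[float, float]     # arc-length interval (mm) on the centreline
    fa_reduction: float           # mean FA decrement at baseline
    affected_groups: tuple[str, ...]


@dataclass
class AtrophySpec:
    """Multiplicative GM reduction inside one atlas label for given groups."""

    label_name: str
    factor: float                 # e.g. 0.85 = 15% volume loss
    affected_groups: tuple[str, ...]


@dataclass
class ScoreModel:
    """FTLD-CDR sum of boxes = slope * lesion depth + intercept + noise."""

    slope: float = 40.0           # score units per FA-unit of lesion depth
    intercept: float = 0.5
    noise_sd: float = 1.178       # yields a designed FA-score correlation near -0.7
                                  # under the default severity spread


@dataclass
class GradientTable:
    """Diffusion gradient scheme: unit directions + b-values (s/mm^2)."""

    directions: np.ndarray        # (N, 3)
    b_values: np.ndarray          # (N,)

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.directions.shape != (len(self.b_values), 3):
            raise ValueError("directions must be (N, 3) matching b_values")
        nz = self.b_values > 0
        if np.sum(~nz) != 1:
            raise ValueError("exactly one b=0 entry is required")
        bs = np.unique(self.b_values[nz])
        if len(bs) != 1:
            raise ValueError("all non-zero b-values must equal the protocol b")
        norms = np.linalg.norm(self.directions[nz], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("non-zero-b directions must be unit vectors")

    @property
    def b(self) -> float:
        return float(self.b_values.max())

    def save(self, prefix) -> None:
        """FSL-style: <prefix>.bvec (3 rows) and <prefix>.bval (1 row)."""
        prefix = str(prefix)
        np.savetxt(prefix + ".bvec", self.directions.T, fmt="%.8f")
        np.savetxt(prefix + ".bval", self.b_values[None, :], fmt="%.1f")

    @classmethod
    def load(cls, prefix) -> "GradientTable":
        prefix = str(prefix)
        bvec = np.loadtxt(prefix + ".bvec").reshape(3, -1).T
        bval = np.atleast_1d(np.loadtxt(prefix + ".bval")).ravel()
        return cls(bvec, bval)


def sphere_directions(n: int, n_iter: int = 80) -> np.ndarray:
    """n roughly uniform unit vectors: Fibonacci-sphere start + antipodal repulsion."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    for _ in range(n_iter):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):  # antipodally symmetric energy
            diff = pts[:, None, :] - sign * pts[None, :, :]
            d2 = np.sum(diff ** 2, axis=-1) + np.eye(n)
            np.maximum(d2, 1e-6, out=d2)
            force += np.sum(diff / d2[..., None] ** 1.5, axis=1)
        pts = pts + 0.005 * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def protocol_gradient_table(n_directions: int, b: float = 1000.0) -> GradientTable:
    """Protocol with ``n_directions`` entries including one b=0 (e.g. 31 or 65)."""
    dirs = np.vstack([np.zeros(3), sphere_directions(n_directions - 1)])
    bvals = np.full(n_directions, b)
    bvals[0] = 0.0
    return GradientTable(dirs, bvals)


@dataclass
class PhantomSpec:
    """Full description of the synthetic study: geometry, effects, cohort."""

    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tracts: list[TractGeometry] = field(default_factory=list)
    lesions: list[LesionSpec] = field(default_factory=list)
    atrophy: list[AtrophySpec] = field(default_factory=list)
    center_offset: float = 0.05           # additive FA offset for center-B scans
    age_slope: float = 0.001              # FA decline per year inside tracts
    reference_age: float = 60.0
    groups: list[tuple[str, int, float, float]] = field(default_factory=lambda: [
        ("control", 39, 57.9, 11.6),
        ("nfppa", 29, 60.4, 5.0),
        ("svppa", 27, 62.4, 10.4),
    ])
    # fraction of each group scanned at center A (remainder at center B)
    center_a_fraction: dict = field(default_factory=lambda: {
        "control": 15 / 39, "nfppa": 26 / 29, "svppa": 23 / 27})
    followup_groups: dict = field(default_factory=lambda: {"nfppa": 10, "svppa": 6})
    followup_progression: float = 0.3     # fractional lesion-depth/extent increase
    score_model: ScoreModel = field(default_factory=ScoreModel)
    background_md: float = 0.7667e-3      # isotropic background diffusivity
    subject_fa_sd: float = 0.01           # biological between-subject FA level
    fa_noise_sd: float = 0.03             # voxel noise on directly sampled FA maps
    dwi_noise_sd: float = 33.0            # additive signal noise at s0=1000 (SNR~30)
    s0: float = 1000.0
    severity_range: tuple[float, float] = (0.5, 1.5)
    atrophy_noise_sd: float = 0.03        # multiplicative volumetric noise
    head_size_sd: float = 0.05            # per-subject global scale on tissue maps
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        names = {t.name for t in self.tracts}
        for les in self.lesions:
            if les.tract_name not in names:
                raise ValueError(f"lesion references unknown tract {les.tract_name!r}")
            if les.fa_reduction <= 0:
                raise ValueError("fa_reduction must be positive")
        if self.followup_progression < 0:
            raise ValueError("followup_progression must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size, shape=self.grid_shape)

    def group_names(self) -> list[str]:
        return [g[0] for g in self.groups]


def default_tracts() -> list[TractGeometry]:
    """Four well-separated tubes standing in for study tracts of interest."""
    def line(p0, p1, n=65):
        return np.linspace(p0, p1, n)
    return [
        TractGeometry("cc_ii", line((-32, 14, 8), (32, 14, 8)), radius=5.0),
        TractGeometry("left_ilf", line((-24, -36, -8), (-24, 36, -8)), radius=5.0),
        TractGeometry("right_ilf", line((24, -36, -8), (24, 36, -8)), radius=5.0),
        TractGeometry("cingulum", line((0, -30, 24), (0, 30, 24)), radius=4.0),
    ]


def default_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The study phantom: lesioned cc_ii for nfPPA, lesioned left ILF for svPPA."""
    kwargs = dict(
        tracts=default_tracts(),
        lesions=[
            LesionSpec("cc_ii", (12.0, 52.0), 0.10, ("nfppa",)),
            LesionSpec("left_ilf", (16.0, 56.0), 0.10, ("svppa",)),
        ],
        atrophy=[
            AtrophySpec("left_frontal", 0.85, ("nfppa",)),
            AtrophySpec("left_temporal", 0.85, ("svppa",)),
        ],
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


# --------------------------------------------------------------------------
# geometry rasterisation (cached per spec instance)
# --------------------------------------------------------------------------

class PhantomGeometry:
    """Voxelised view of the tract layout: nearest tract, distance, tangent."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        shape = spec.grid_shape
        aff = spec.affine
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
        world = vox @ aff[:3, :3].T + aff[:3, 3]

        lo = aff[:3, 3] - np.asarray(spec.voxel_size) / 2
        hi = lo + np.asarray(spec.voxel_size) * np.asarray(shape)

        n_vox = world.shape[0]
        self.dist = np.full(n_vox, np.inf)
        self.tract_id = np.full(n_vox, -1, dtype=int)
        self.tangent = np.zeros((n_vox, 3))
        self.arclength = np.zeros(n_vox)

        for t_idx, tract in enumerate(spec.tracts):
            pts, tans, arcs = _densify(tract.centerline, step=0.5)
            if np.any(pts - tract.radius < lo) or np.any(pts + tract.radius > hi):
                raise ValueError(f"tract {tract.name!r} leaves the grid")
            tree = cKDTree(pts)
            d, idx = tree.query(world)
            # nearest-centreline rule resolves overlapping tracts
            closer = d < self.dist
            inside = closer & (d <= tract.radius)
            self.dist[closer] = d[closer]
            self.tract_id[inside] = t_idx
            self.tangent[inside] = tans[idx[inside]]
            self.arclength[inside] = arcs[idx[inside]]

        self.shape = shape
        self.world = world

    def tract_mask(self, name: str) -> np.ndarray:
        t_idx = [t.name for t in self.spec.tracts].index(name)
        return (self.tract_id == t_idx).reshape(self.shape)

    def support_mask(self) -> np.ndarray:
        return (self.tract_id >= 0).reshape(self.shape)

    def lesion_mask(self, lesion: LesionSpec, progression: float = 0.0) -> np.ndarray:
        """Voxels inside the lesioned span (span widened by ``progression``)."""
        t_idx = [t.name for t in self.spec.tracts].index(lesion.tract_name)
        lo, hi = lesion.span
        if progression > 0:
            c, half = (lo + hi) / 2, (hi - lo) / 2 * (1 + progression)
            lo, hi = c - half, c + half
        sel = (self.tract_id == t_idx) & (self.arclength >= lo) & (self.arclength <= hi)
        return sel.reshape(self.shape)


def _densify(polyline: np.ndarray, step: float):
    """Resample a polyline every ``step`` mm; return points, tangents, arclengths."""
    seg = np.diff(polyline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.arange(0.0, total + step / 2, step)
    pts = np.empty((len(s), 3))
    tans = np.empty((len(s), 3))
    j = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[j]) / np.where(seg_len[j] > 0, seg_len[j], 1.0)
    pts = polyline[j] + frac[:, None] * seg[j]
    tans = seg[j] / np.where(seg_len[j] > 0, seg_len[j], 1.0)[:, None]
    return pts, tans, s


_GEOM_CACHE: dict[int, PhantomGeometry] = {}


def geometry(spec: PhantomSpec) -> PhantomGeometry:
    key = id(spec)
    if key not in _GEOM_CACHE:
        if len(_GEOM_CACHE) > 8:
            _GEOM_CACHE.clear()
        _GEOM_CACHE[key] = PhantomGeometry(spec)
    return _GEOM_CACHE[key]


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

def subject_rng(spec: PhantomSpec, subject_id: str, *salt: int) -> np.random.Generator:
    """Deterministic per-subject stream keyed on spec seed + id + purpose salt."""
    return np.random.default_rng(
        [int(spec.seed) & 0x7FFFFFFF, zlib.crc32(subject_id.encode()) & 0x7FFFFFFF, *salt])


def make_cohort(spec: PhantomSpec) -> pd.DataFrame:
    """Subject table: id, group, age, sex, center, timepoint (scores unset)."""
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 11])
    rows = []
    for g_name, n, mean_age, sd_age in spec.groups:
        n_a = int(round(spec.center_a_fraction.get(g_name, 0.5) * n))
        for i in range(n):
            sid = f"{g_name}_{i:03d}"
            age = float(np.clip(rng.normal(mean_age, sd_age), 35.0, 90.0))
            sex = "m" if rng.random() < 0.5 else "f"
            center = "A" if i < n_a else "B"
            severity = float(rng.uniform(*spec.severity_range))
            head = float(np.clip(rng.normal(1.0, spec.head_size_sd), 0.8, 1.2))
            fa_off = float(rng.normal(0.0, spec.subject_fa_sd))
            rows.append(dict(subject_id=sid, group=g_name, age=age, sex=sex,
                             center=center, timepoint=BASELINE,
                             severity=severity, head_size=head,
                             fa_offset=fa_off))
    df = pd.DataFrame(rows)
    # follow-up subset: center-A patients first (mirroring the longitudinal
    # sub-cohort), topped up from center B if the group has too few at A
    fu_rows = []
    for g_name, n_fu in spec.followup_groups.items():
        grp = df[df.group == g_name]
        cand = pd.concat([grp[grp.center == "A"], grp[grp.center == "B"]]).head(n_fu)
        for _, r in cand.iterrows():
            r2 = r.copy()
            r2["timepoint"] = FOLLOWUP
            r2["age"] = r["age"] + 1.0
            fu_rows.append(r2)
    if fu_rows:
        df = pd.concat([df, pd.DataFrame(fu_rows)], ignore_index=True)
    return df


def lesion_depth(spec: PhantomSpec, subject, timepoint: str = BASELINE) -> float:
    """Total planted FA decrement for one subject (sum over affecting lesions)."""
    depth = 0.0
    for les in spec.lesions:
        if subject["group"] in les.affected_groups:
            d = les.fa_reduction * float(subject.get("severity", 1.0))
            if timepoint == FOLLOWUP:
                d *= 1.0 + spec.followup_progression
            depth += d
    return depth


def assign_scores(spec: PhantomSpec, cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach MMSE and FTLD-CDR sum-of-boxes; controls score 0, scores >= 0."""
    cohort = cohort.copy()
    sob, mmse = [], []
    for _, row in cohort.iterrows():
        rng = subject_rng(spec, row["subject_id"], 23)
        depth = lesion_depth(spec, row, row["timepoint"])
        if row["group"] == "control" or depth == 0.0:
            s = 0.0
            m = float(np.clip(rng.normal(28.0, 1.2), 0, 30))
        else:
            sm = spec.score_model
            s = sm.slope * depth + sm.intercept + rng.normal(0.0, sm.noise_sd)
            s = float(max(s, 0.0))
            m = float(np.clip(rng.normal(25.0 - 20.0 * depth, 2.0), 0, 30))
        sob.append(s)
        mmse.append(round(m, 1))
    cohort["ftld_cdr_sob"] = sob
    cohort["mmse"] = mmse
    return cohort


# --------------------------------------------------------------------------
# diffusion substrate
# --------------------------------------------------------------------------

def _lesioned_eigenvalues(lam_par: float, lam_perp: float, delta_fa: float) -> np.ndarray:
    """Trace-preserving eigenvalue shrinkage giving FA = FA0 - delta_fa."""
    lam = np.array([lam_par, lam_perp, lam_perp])
    mean = lam.mean()
    dev = lam - mean
    k = np.linalg.norm(dev)
    if k == 0:
        return lam
    fa0 = float(fa_from_eigenvalues(lam))
    target = max(fa0 - delta_fa, 0.0)
    m = np.sqrt(3.0) * mean
    u = target * m / np.sqrt(1.5 - target ** 2)
    scale = min(u / k, 1.0)
    return mean + scale * dev


def build_tensor_field(spec: PhantomSpec, subject, timepoint: str = BASELINE) -> TensorField:
    """Ground-truth tensor field for one subject scan.

    Background voxels are isotropic at the background diffusivity; tube
    voxels carry a cylinder-aligned tensor (lambda_parallel along the local
    centreline tangent); lesioned spans are shrunk toward isotropy so FA
    drops by the subject's lesion depth. Deterministic: no noise here.
    """
    geom = geometry(spec)
    shape = spec.grid_shape
    n_vox = int(np.prod(shape))
    mats = np.zeros((n_vox, 3, 3))
    iso = np.eye(3) * spec.background_md
    mats[:] = iso

    depth_map = np.zeros(n_vox)
    for les in spec.lesions:
        if subject["group"] in les.affected_groups:
            prog = spec.followup_progression if timepoint == FOLLOWUP else 0.0
            mask = geom.lesion_mask(les, progression=prog).reshape(-1)
            d = les.fa_reduction * float(subject.get("severity", 1.0))
            if timepoint == FOLLOWUP:
                d *= 1.0 + spec.followup_progression
            depth_map[mask] += d

    inside = geom.tract_id >= 0
    idx = np.nonzero(inside)[0]
    for v in idx:
        tract = spec.tracts[geom.tract_id[v]]
        lam = _lesioned_eigenvalues(tract.lambda_parallel, tract.lambda_perp,
                                    depth_map[v]) if depth_map[v] > 0 else \
            np.array([tract.lambda_parallel, tract.lambda_perp, tract.lambda_perp])
        e1 = geom.tangent[v]
        # orthonormal frame around the tangent
        ref = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(e1, ref)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        V = np.stack([e1, e2, e3], axis=1)
        mats[v] = V @ np.diag(lam) @ V.T

    mats = mats.reshape(shape + (3, 3))
    return TensorField.from_matrices(mats, spec.affine)


def simulate_dwi(field: TensorField, gtab: GradientTable, s0: float = 1000.0,
                 noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Monoexponential DWI signal S = s0 exp(-b g^T D g) + Gaussian noise."""
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    D = field.as_matrices()
    g = gtab.directions
    b = gtab.b_values
    # quadratic form per voxel and direction
    q = np.einsum("nd,...de,ne->...n", g, D, g)
    signal = s0 * np.exp(-b * q)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return signal


def ground_truth_fa(spec: PhantomSpec, subject, timepoint: str = BASELINE) -> ScalarMap:
    """Noise-free FA map implied by the phantom construction (no age/center effects)."""
    geom = geometry(spec)
    shape = spec.grid_shape
    fa = np.zeros(int(np.prod(shape)))
    depth_map = np.zeros_like(fa)
    for les in spec.lesions:
        if subject["group"] in les.affected_groups:
            prog = spec.followup_progression if timepoint == FOLLOWUP else 0.0
            mask = geom.lesion_mask(les, progression=prog).reshape(-1)
            d = les.fa_reduction * float(subject.get("severity", 1.0))
            if timepoint == FOLLOWUP:
                d *= 1.0 + spec.followup_progression
            depth_map[mask] += d
    inside = geom.tract_id >= 0
    tract_fa = np.array([t.fa for t in spec.tracts])
    fa[inside] = tract_fa[geom.tract_id[inside]] - depth_map[inside]
    return ScalarMap(np.clip(fa, 0, 1).reshape(shape), spec.affine, tag="fa")


def apply_subject_effects(fa: ScalarMap, spec: PhantomSpec, subject,
                          apply_center_effect: bool = True,
                          apply_age_effect: bool = True) -> ScalarMap:
    """Add the subject's biological FA level, age decline, and center-B
    offset inside the tract support."""
    out = fa.data.copy()
    support = geometry(spec).support_mask()
    offset = float(subject.get("fa_offset", 0.0))
    if apply_age_effect:
        offset -= spec.age_slope * (float(subject["age"]) - spec.reference_age)
    if apply_center_effect and subject["center"] == "B":
        offset += spec.center_offset
    out[support] += offset
    return fa.like(np.clip(out, 0, 1))


def sample_fa_map(spec: PhantomSpec, subject, timepoint: str = BASELINE,
                  apply_center_effect: bool = True,
                  apply_age_effect: bool = True,
                  rng: np.random.Generator | None = None) -> ScalarMap:
    """Observed FA map: truth + age decline + center offset + voxel noise.

    The age and center effects act inside the tract support (background FA
    is pinned near zero either way); noise is white Gaussian on every voxel.
    This is the fast sampling route used by the statistical stages; the
    DWI-simulation route produces equivalent maps through the tensor fit.
    """
    if rng is None:
        rng = subject_rng(spec, str(subject["subject_id"]),
                          41 if timepoint == BASELINE else 42)
    fa = apply_subject_effects(ground_truth_fa(spec, subject, timepoint), spec,
                               subject, apply_center_effect, apply_age_effect)
    noisy = fa.data + rng.normal(0.0, spec.fa_noise_sd, size=fa.data.shape)
    return ScalarMap(np.clip(noisy, 0, 1), spec.affine, tag="fa")


# --------------------------------------------------------------------------
# tissue-component maps, atlas, volumetry ground truth
# --------------------------------------------------------------------------

SOI_LABELS = {
    1: "left_frontal", 2: "right_frontal",
    3: "left_temporal", 4: "right_temporal",
    5: "left_parietal", 6: "right_parietal",
    7: "subcortical",
}


def _brain_mask(spec: PhantomSpec) -> np.ndarray:
    shape = np.asarray(spec.grid_shape, dtype=float)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in spec.grid_shape], indexing="ij")
    c = (shape - 1) / 2
    r = shape / 2 - 1.5
    d2 = (((ii - c[0]) / r[0]) ** 2 + ((jj - c[1]) / r[1]) ** 2
          + ((kk - c[2]) / r[2]) ** 2)
    return d2 <= 1.0


def build_atlas(spec: PhantomSpec) -> ScalarMap:
    """Deterministic parcellation of the brain ellipsoid into named SOIs."""
    brain = _brain_mask(spec)
    sx, sy, sz = spec.grid_shape
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in spec.grid_shape], indexing="ij")
    left = ii < sx / 2
    frontal = jj >= 0.62 * sy
    temporal = (jj < 0.38 * sy) & (kk < sz / 2)
    parietal = (jj < 0.38 * sy) & (kk >= sz / 2)
    core = (~frontal & ~temporal & ~parietal
            & (np.abs(ii - sx / 2) < 0.22 * sx)
            & (np.abs(kk - sz / 2) < 0.25 * sz))
    labels = np.zeros(spec.grid_shape, dtype=float)
    labels[left & frontal] = 1
    labels[~left & frontal] = 2
    labels[left & temporal] = 3
    labels[~left & temporal] = 4
    labels[left & parietal] = 5
    labels[~left & parietal] = 6
    labels[core] = 7
    labels[~brain] = 0
    return ScalarMap(labels, spec.affine, tag="mask")


def build_component_maps(spec: PhantomSpec, subject, timepoint: str = BASELINE,
                         rng: np.random.Generator | None = None):
    """(GM, WM, CSF) probability maps + atlas for one subject scan.

    Maps arrive "normalized and modulated": group-specific atrophy is a
    multiplicative GM reduction inside designated labels, the subject's
    head size scales all compartments, and small multiplicative noise is
    applied. GM+WM+CSF <= 1 everywhere.
    """
    if rng is None:
        rng = subject_rng(spec, str(subject["subject_id"]),
                          61 if timepoint == BASELINE else 62)
    brain = _brain_mask(spec).astype(float)
    smooth_brain = ndimage.gaussian_filter(brain, 1.0)
    gm = 0.55 * smooth_brain
    wm = 0.33 * smooth_brain
    csf = 0.08 * smooth_brain

    atlas = build_atlas(spec)
    for atro in spec.atrophy:
        if subject["group"] in atro.affected_groups:
            label = {v: k for k, v in SOI_LABELS.items()}[atro.label_name]
            loss = (1.0 - atro.factor) * float(subject.get("severity", 1.0))
            if timepoint == FOLLOWUP:
                loss *= 1.0 + spec.followup_progression
            factor = max(1.0 - loss, 0.0)
            sel = atlas.data == label
            # atrophied tissue becomes CSF: the intracranial volume is conserved
            csf[sel] += gm[sel] * (1.0 - factor)
            gm[sel] *= factor

    head = float(subject.get("head_size", 1.0))
    noise = rng.normal(1.0, spec.atrophy_noise_sd)
    gm = gm * head * noise
    wm = wm * head * rng.normal(1.0, spec.atrophy_noise_sd)
    csf = csf * head * rng.normal(1.0, spec.atrophy_noise_sd)

    gm = np.clip(gm, 0, 1)
    wm = np.clip(wm, 0, 1)
    csf = np.clip(csf, 0, 1)
    total = gm + wm + csf
    over = total > 1.0
    if np.any(over):  # renormalise the rare voxels pushed past unity
        gm[over] /= total[over]
        wm[over] /= total[over]
        csf[over] /= total[over]
    aff = spec.affine
    return (ScalarMap(gm, aff, "component"), ScalarMap(wm, aff, "component"),
            ScalarMap(csf, aff, "component"), atlas)


# --------------------------------------------------------------------------
# truth bookkeeping and on-disk cohort
# --------------------------------------------------------------------------

def truth_summary(spec: PhantomSpec, cohort: pd.DataFrame) -> dict:
    """Ground-truth record for tests: lesion masks, depths, atrophy factors."""
    geom = geometry(spec)
    per_subject = {}
    for _, row in cohort.iterrows():
        key = f"{row['subject_id']}@{row['timepoint']}"
        per_subject[key] = {
            "lesion_depth": lesion_depth(spec, row, row["timepoint"]),
            "severity": float(row.get("severity", 1.0)),
            "atrophy": {
                a.label_name: max(1.0 - (1.0 - a.factor) * float(row.get("severity", 1.0))
                                  * ((1.0 + spec.followup_progression)
                                     if row["timepoint"] == FOLLOWUP else 1.0), 0.0)
                for a in spec.atrophy if row["group"] in a.affected_groups},
        }
    lesion_masks = {
        f"{les.tract_name}:{i}": geom.lesion_mask(les).astype(int).tolist()
        for i, les in enumerate(spec.lesions)}
    return {"per_subject": per_subject,
            "lesion_voxel_counts": {k: int(np.sum(v)) for k, v in
                                    ((k, np.asarray(m)) for k, m in lesion_masks.items())},
            "tract_voxel_counts": {t.name: int(geom.tract_mask(t.name).sum())
                                   for t in spec.tracts}}


def generate_cohort_dataset(spec: PhantomSpec, outdir, write_dwi: bool = False) -> pd.DataFrame:
    """Write the synthetic study to disk: NIfTI maps, gradient tables, cohort TSV,
    truth JSON. Returns the scored cohort table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = assign_scores(spec, make_cohort(spec))
    cohort.drop(columns=["severity", "head_size", "fa_offset"]).to_csv(
        outdir / "cohort.tsv", sep="\t", index=False)

    protocol = {"A": protocol_gradient_table(31), "B": protocol_gradient_table(65)}
    for c, gt in protocol.items():
        gt.save(outdir / f"protocol_{c}")

    for _, row in cohort.iterrows():
        tag = f"{row['subject_id']}_{row['timepoint']}"
        fa = sample_fa_map(spec, row, row["timepoint"])
        fa.save(outdir / f"{tag}_fa.nii.gz")
        gm, wm, csf, atlas = build_component_maps(spec, row, row["timepoint"])
        gm.save(outdir / f"{tag}_gm.nii.gz")
        wm.save(outdir / f"{tag}_wm.nii.gz")
        csf.save(outdir / f"{tag}_csf.nii.gz")
        if write_dwi:
            field = build_tensor_field(spec, row, row["timepoint"])
            dwi = simulate_dwi(field, protocol[row["center"]], s0=spec.s0,
                               noise_sd=spec.dwi_noise_sd,
                               rng=subject_rng(spec, row["subject_id"], 71))
            import nibabel as nib
            nib.save(nib.Nifti1Image(dwi, spec.affine),
                     str(outdir / f"{tag}_dwi.nii.gz"))
    build_atlas(spec).save(outdir / "atlas.nii.gz")
    with open(outdir / "atlas_labels.json", "w") as fh:
        json.dump(SOI_LABELS, fh, indent=1)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_summary(spec, cohort), fh)
    return cohort
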