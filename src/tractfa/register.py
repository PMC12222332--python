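"""Spatial normalization: affine registration, halfway longitudinal alignment,
iterative template normalization, and FA smoothing.

Registration maximizes the normalized correlation coefficient between a fixed
and a resampled moving image over a 12-parameter affine (translation,
rotation, log-scale, shear), with a two-level multi-resolution schedule.
Longitudinal pairs are aligned with *halfway* matrices — each timepoint moves
through the matrix square root of the full transform, so neither scan suffers
more interpolation than the other. Template normalization is iterative: the
first pass registers the b=0 image to the b=0 template, later passes register
the FA map to the FA template (higher tissue contrast), and the loop halts
once the FA correlation exceeds a threshold (default 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.linalg import expm, logm

from .grids import ScalarMap

CORR_THRESHOLD_DEFAULT = 0.7
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RegistrationResult:
    transform: np.ndarray      # 4x4 world->world, maps moving into fixed frame
    similarity: float          # normalized correlation at the optimum


@dataclass
class NormalizationResult:
    transform: np.ndarray
    normalized_fa: ScalarMap
    iterations_used: int
    correlation: float
    flagged: bool


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized correlation coefficient of two arrays (0 if degenerate)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def params_to_affine(params: np.ndarray) -> np.ndarray:
    """[tx ty tz, rx ry rz (rad), log-scale x3, shear xy xz yz] -> 4x4."""
    t = params[0:3]
    rx, ry, rz = params[3:6]
    scale = np.exp(params[6:9])
    hxy, hxz, hyz = params[9:12]
    Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
    Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
    Rz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
    Sh = np.array([[1, hxy, hxz], [0, 1, hyz], [0, 0, 1]])
    A = Rz @ Ry @ Rx @ Sh @ np.diag(scale)
    out = np.eye(4)
    out[:3, :3] = A
    out[:3, 3] = t
    return out


def resample(moving: ScalarMap, transform: np.ndarray, order: int = 1,
             reference: ScalarMap | None = None) -> ScalarMap:
    """Value at world w of the output is moving(T^-1 w), on the reference grid."""
    ref = reference if reference is not None else moving
    vox_map = (np.linalg.inv(moving.affine) @ np.linalg.inv(transform) @ ref.affine)
    data = ndimage.affine_transform(moving.data, vox_map[:3, :3], vox_map[:3, 3],
                                    output_shape=ref.shape, order=order,
                                    mode="constant", cval=0.0)
    return ScalarMap(data, ref.affine.copy(), moving.tag)


def _downsample(m: ScalarMap, factor: int) -> ScalarMap:
    if factor == 1:
        return m
    sm = ndimage.gaussian_filter(m.data, sigma=factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    aff = m.affine.copy()
    aff[:3, :3] *= factor
    return ScalarMap(data, aff, m.tag)


def register_affine(fixed: ScalarMap, moving: ScalarMap,
                    dof: int = 12, levels: tuple[int, ...] = (2, 1),
                    x0: np.ndarray | None = None) -> RegistrationResult:
    """Estimate the world-to-world affine carrying ``moving`` onto ``fixed``.

    dof: 6 rigid, 9 rigid+scale, 12 full affine. Powell optimization of
    1 - NCC at each resolution level, coarse to fine.
    """
    if dof not in (6, 9, 12):
        raise ValueError("dof must be 6, 9, or 12")
    params = np.zeros(12) if x0 is None else np.array(x0, dtype=float)

    for level in levels:
        f = _downsample(fixed, level)
        m = _downsample(moving, level)

        def cost(p12_active):
            p = params.copy()
            p[:dof] = p12_active
            T = params_to_affine(p)
            warped = resample(m, T, order=1, reference=f)
            return 1.0 - ncc(f.data, warped.data)

        res = optimize.minimize(cost, params[:dof], method="Powell",
                                options={"xtol": 1e-5, "ftol": 1e-9,
                                         "maxiter": 60})
        params[:dof] = res.x

    T = params_to_affine(params)
    if np.linalg.det(T[:3, :3]) < 0:
        raise ValueError("registration produced a reflecting transform")
    warped = resample(moving, T, order=1, reference=fixed)
    return RegistrationResult(T, ncc(fixed.data, warped.data))


def matrix_sqrt_affine(T: np.ndarray) -> np.ndarray:
    """Principal square root of a homogeneous affine via logm/expm."""
    L = logm(np.asarray(T, dtype=complex))
    H = expm(0.5 * L)
    return np.real(H)


def halfway_register(baseline: ScalarMap, followup: ScalarMap,
                     dof: int = 6) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align a longitudinal pair without baseline bias.

    Estimates T mapping followup onto baseline, then returns
    (T_half_base, T_half_follow, T) with T_half_follow = T^(1/2) and
    T_half_base = T^(-1/2): each image moves half the distance, so the
    composition of the halves reproduces T.
    """
    res = register_affine(baseline, followup, dof=dof)
    T = res.transform
    if np.linalg.det(T[:3, :3]) <= 0:
        raise ValueError("halfway registration requires a positive-determinant transform")
    T_half_follow = matrix_sqrt_affine(T)
    T_half_base = np.linalg.inv(T_half_follow)
    return T_half_base, T_half_follow, T


@dataclass
class TemplatePair:
    b0_template: ScalarMap
    fa_template: ScalarMap

    def __post_init__(self) -> None:
        if self.b0_template.shape != self.fa_template.shape:
            raise ValueError("template pair must share geometry")


def build_templates(control_maps: list[tuple[ScalarMap, ScalarMap]]) -> TemplatePair:
    """Voxel-wise arithmetic mean of aligned control (b0, FA) pairs."""
    if not control_maps:
        raise ValueError("need at least one control map pair")
    b0s = np.stack([b.data for b, _ in control_maps])
    fas = np.stack([f.data for _, f in control_maps])
    ref_b0, ref_fa = control_maps[0]
    return TemplatePair(ref_b0.like(b0s.mean(axis=0), "b0"),
                        ref_fa.like(fas.mean(axis=0), "fa"))


def normalize_to_template(subject_fa: ScalarMap, subject_b0: ScalarMap,
                          templates: TemplatePair, max_iter: int = 4,
                          corr_threshold: float = CORR_THRESHOLD_DEFAULT
                          ) -> NormalizationResult:
    """Iterative normalization to the study template.

    Pass 1 registers b0 -> b0 template; later passes register the current
    normalized FA -> FA template, composing transforms. Stops when the FA
    correlation exceeds ``corr_threshold``; a subject that never reaches it
    is flagged (quality-control failure) rather than silently accepted.
    """
    T = np.eye(4)
    iterations = 0
    corr = ncc(templates.fa_template.data, subject_fa.data)
    for it in range(max_iter):
        if it == 0:
            res = register_affine(templates.b0_template, subject_b0)
            T = res.transform
        else:
            current = resample(subject_fa, T, reference=templates.fa_template)
            res = register_affine(templates.fa_template, current)
            T = res.transform @ T
        iterations = it + 1
        normalized = resample(subject_fa, T, reference=templates.fa_template)
        corr = ncc(templates.fa_template.data, normalized.data)
        if corr > corr_threshold:
            break
    normalized = resample(subject_fa, T, reference=templates.fa_template)
    flagged = corr <= corr_threshold
    return NormalizationResult(T, normalized, iterations, corr, flagged)


def smooth(fa: ScalarMap, fwhm_mm: float = 8.0,
           mask: np.ndarray | None = None) -> ScalarMap:
    """Isotropic 3-D Gaussian smoothing specified by FWHM in millimetres.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxels by the
    map's voxel size; zero padding at the boundary. With ``mask`` given,
    smoothing is renormalized inside the mask (smooth(f*m)/smooth(m)) so
    edge voxels are not diluted toward zero.
    """
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / fa.voxel_size
    if mask is None:
        return fa.like(ndimage.gaussian_filter(fa.data, sigma=sigma_vox))
    m = mask.astype(float)
    num = ndimage.gaussian_filter(fa.data * m, sigma=sigma_vox)
    den = ndimage.gaussian_filter(m, sigma=sigma_vox)
    out = np.zeros_like(num)
    inside = den > 1e-8
    out[inside] = num[inside] / den[inside]
    out[~mask.astype(bool)] = 0.0
    return fa.like(out)


def save_transform(T: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(T, dtype=float), fmt="%.17g")


def load_transform(path) -> np.ndarray:
    T = np.loadtxt(str(path))
    if T.shape != (4, 4):
        raise ValueError("transform file must hold a 4x4 matrix")
    return T
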