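"""Diffusion-tensor estimation, fractional anisotropy, and reorientation.

The tensor is fitted voxel-wise by log-linear least squares of the
monoexponential signal model ln S = ln S0 - b * g^T D g. Fractional
anisotropy follows the standard definition

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||

on eigenvalues clamped at zero (negative eigenvalues can only arise from
noise and would otherwise push FA above 1). Tensors are reoriented under
spatial transforms with the finite-strain rule: the rotation R extracted
from the affine by polar decomposition is applied as D' = R D R^T, so
directional information survives normalization.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import ScalarMap, TensorField


def _design_matrix(gtab) -> np.ndarray:
    """Rows: [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]."""
    g = np.asarray(gtab.directions, dtype=float)
    b = np.asarray(gtab.b_values, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    cols = np.stack([
        np.ones_like(b),
        -b * gx * gx,
        -b * gy * gy,
        -b * gz * gz,
        -2 * b * gx * gy,
        -2 * b * gx * gz,
        -2 * b * gy * gz,
    ], axis=1)
    return cols


def fit_tensor(dwi: np.ndarray, gtab, affine: np.ndarray) -> TensorField:
    """Fit a diffusion tensor per voxel from a DWI series.

    Parameters
    ----------
    dwi : array, shape (X, Y, Z, n_gradients)
        One volume per gradient-table entry.
    gtab : GradientTable
        Directions and b-values matching the last axis of ``dwi``.
    affine : 4x4 world affine of the grid.

    Returns
    -------
    TensorField with ``mask`` False wherever any signal was non-positive
    (those voxels get a zero tensor).
    """
    dwi = np.asarray(dwi, dtype=np.float64)
    if dwi.ndim != 4 or dwi.shape[-1] != len(gtab.b_values):
        raise ValueError("dwi last axis must match the gradient table length")
    n_dwi = int(np.sum(np.asarray(gtab.b_values) > 0))
    if n_dwi < 6 or len(gtab.b_values) - n_dwi < 1:
        raise ValueError("need at least 6 non-zero-b directions and one b=0 volume")

    X = _design_matrix(gtab)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            f"rank-deficient gradient design (rank {np.linalg.matrix_rank(X)} < 7) "
            f"for table with {len(gtab.b_values)} entries")
    pinv = np.linalg.pinv(X)

    valid = np.all(dwi > 0, axis=-1)
    logs = np.zeros_like(dwi)
    np.log(dwi, out=logs, where=dwi > 0)
    # coefficients: (7, n_voxels) -> tensor comps in (dxx,dyy,dzz,dxy,dxz,dyz)
    coef = np.tensordot(logs, pinv, axes=([-1], [-1]))
    tensor = np.zeros(dwi.shape[:3] + (6,), dtype=np.float64)
    # reorder to upper-tri (dxx, dxy, dxz, dyy, dyz, dzz)
    tensor[..., 0] = coef[..., 1]
    tensor[..., 1] = coef[..., 4]
    tensor[..., 2] = coef[..., 5]
    tensor[..., 3] = coef[..., 2]
    tensor[..., 4] = coef[..., 6]
    tensor[..., 5] = coef[..., 3]
    tensor[~valid] = 0.0
    return TensorField(tensor, np.asarray(affine, dtype=float), mask=valid)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA of eigenvalue triples (last axis length 3), clamped at zero."""
    lam = np.clip(np.asarray(evals, dtype=np.float64), 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_fa(field: TensorField) -> ScalarMap:
    """Fractional anisotropy map of a tensor field (0 at degenerate voxels)."""
    fa = fa_from_eigenvalues(field.eigenvalues())
    if field.mask is not None:
        fa = np.where(field.mask, fa, 0.0)
    return ScalarMap(fa, field.affine.copy(), tag="fa")


def rotation_from_affine(transform: np.ndarray) -> np.ndarray:
    """Finite-strain rotation: polar-decomposition factor of the linear part."""
    A = np.asarray(transform, dtype=float)[:3, :3]
    det = np.linalg.det(A)
    if abs(det) < 1e-12:
        raise ValueError("singular transform cannot be applied to a tensor field")
    U, _, Vt = np.linalg.svd(A)
    R = U @ Vt
    if np.linalg.det(R) < 0:  # keep a proper rotation
        U[:, -1] *= -1
        R = U @ Vt
    return R


def reorient(field: TensorField, transform: np.ndarray, order: int = 1) -> TensorField:
    """Resample a tensor field under a world-to-world affine and reorient it.

    The output lives on the same grid; the value at world position w is
    R D(T^-1 w) R^T with R the finite-strain rotation of ``transform``.
    Trilinear interpolation acts on the six tensor components.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4) or abs(np.linalg.det(transform)) < 1e-12:
        raise ValueError("transform must be an invertible 4x4 matrix")
    R = rotation_from_affine(transform)

    # voxel -> voxel pullback: A^-1 T^-1 A
    vox_map = np.linalg.inv(field.affine) @ np.linalg.inv(transform) @ field.affine
    out = np.empty_like(field.data)
    for c in range(6):
        out[..., c] = ndimage.affine_transform(
            field.data[..., c], vox_map[:3, :3], vox_map[:3, 3],
            order=order, mode="constant", cval=0.0)

    mats = TensorField(out, field.affine).as_matrices()
    rotated = np.einsum("ab,...bc,dc->...ad", R, mats, R)
    new_mask = None
    if field.mask is not None:
        m = ndimage.affine_transform(
            field.mask.astype(np.float64), vox_map[:3, :3], vox_map[:3, 3],
            order=0, mode="constant", cval=0.0)
        new_mask = m > 0.5
    return TensorField.from_matrices(rotated, field.affine.copy(), new_mask)
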