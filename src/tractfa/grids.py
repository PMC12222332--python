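"""Grid-aligned containers for scalar maps and diffusion-tensor fields.

Both containers couple a voxel grid to a world affine (NIfTI convention:
``world = affine @ (i, j, k, 1)``, millimetres). Tensor fields store the six
unique components of the symmetric 3x3 diffusion tensor per voxel in
upper-triangular order (dxx, dxy, dxz, dyy, dyz, dzz), in mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

# upper-triangular index pairs for (dxx, dxy, dxz, dyy, dyz, dzz)
_TRIU_ROWS = np.array([0, 0, 0, 1, 1, 2])
_TRIU_COLS = np.array([0, 1, 2, 1, 2, 2])

SCALAR_TAGS = ("fa", "t", "p", "q", "r", "component", "mask", "b0", "scalar")


@dataclass
class ScalarMap:
    """A 3-D scalar grid (FA map, statistic map, probability map, mask)."""

    data: np.ndarray
    affine: np.ndarray
    tag: str = "scalar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"ScalarMap requires a 3-D array, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def like(self, data: np.ndarray, tag: str | None = None) -> "ScalarMap":
        """A new map on the same grid."""
        return ScalarMap(np.asarray(data, dtype=np.float64), self.affine.copy(), tag or self.tag)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T).T + inv[:3, 3]

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float64), self.affine)
        img.header["descrip"] = f"tractfa scalar map: {self.tag}".encode()[:79]
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, tag: str = "scalar") -> "ScalarMap":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine, tag)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors on a grid with a world affine.

    ``data`` has shape (X, Y, Z, 6) holding (dxx, dxy, dxz, dyy, dyz, dzz).
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError("TensorField data must have shape (X, Y, Z, 6)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric 3x3 matrices, shape (X, Y, Z, 3, 3)."""
        out = np.zeros(self.shape + (3, 3), dtype=np.float64)
        out[..., _TRIU_ROWS, _TRIU_COLS] = self.data
        out[..., _TRIU_COLS, _TRIU_ROWS] = self.data
        return out

    @staticmethod
    def from_matrices(mats: np.ndarray, affine: np.ndarray,
                      mask: np.ndarray | None = None) -> "TensorField":
        mats = np.asarray(mats, dtype=np.float64)
        data = mats[..., _TRIU_ROWS, _TRIU_COLS]
        return TensorField(data, affine, mask)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues per voxel, ascending, shape (X, Y, Z, 3)."""
        return np.linalg.eigvalsh(self.as_matrices())

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues ascending, eigenvectors in columns) per voxel."""
        return np.linalg.eigh(self.as_matrices())

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float64), self.affine)
        img.header["descrip"] = b"tensor upper-tri dxx,dxy,dxz,dyy,dyz,dzz"
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "TensorField":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=np.float64), img.affine)


def default_affine(voxel_size=(2.0, 2.0, 2.0), origin=None, shape=None) -> np.ndarray:
    """Axis-aligned affine; origin defaults to the grid centre at world 0."""
    vs = np.asarray(voxel_size, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    if origin is None:
        if shape is None:
            origin = np.zeros(3)
        else:
            origin = -vs * (np.asarray(shape, dtype=float) - 1) / 2.0
    aff[:3, 3] = origin
    return aff
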