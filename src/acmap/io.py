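"""Volume / gradient-table data model and NIfTI + FSL bval/bvec I/O.

Conventions
-----------
* Voxel indexing is 0-based; a continuous voxel coordinate ``v`` maps to
  world (mm) coordinates via ``affine @ [v, 1]``; voxel centers sit at
  integer coordinates.
* b-values below :data:`B0_THRESHOLD` (s/mm^2) are treated as b=0.
* "Tri-cubic" interpolation means a cubic spline with mirror boundary
  handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.linalg import polar

#: b-values (s/mm^2) below this are flagged as non-diffusion-weighted.
B0_THRESHOLD = 50.0


@dataclass
class Volume:
    """A scalar (or 4D multi-channel) image grid with a voxel->world affine."""

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine contains non-finite entries")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.voxel_size <= 0) or np.any(~np.isfinite(self.voxel_size)):
            raise ValueError("voxel sizes must be positive and finite")
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be 3D or 4D")

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of a voxel along each grid axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape3(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.asarray(vox, dtype=float)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        return world @ inv[:3, :3].T + inv[:3, 3]

    def like(self, data: np.ndarray) -> "Volume":
        """New volume on the same grid with different payload."""
        return Volume(data=data, affine=self.affine.copy(), space_tag=self.space_tag)


@dataclass
class BinaryMask:
    """A {0,1} grid sharing a Volume's shape and affine."""

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of mask voxels."""
        return np.argwhere(self.data > 0)

    def as_volume(self) -> Volume:
        return Volume(self.data.astype(np.float32), self.affine, self.space_tag)


@dataclass
class GradientTable:
    """FSL-style diffusion gradient table (b-values + unit directions)."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)
    b0_flags: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError("bvecs must have shape (n, 3)")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError("bvals and bvecs lengths differ")
        self.b0_flags = self.bvals < B0_THRESHOLD
        if not np.any(self.b0_flags):
            raise ValueError("gradient table has no b=0 entry")
        norms = np.linalg.norm(self.bvecs[~self.b0_flags], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("weighted bvecs must be unit vectors")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def n_b0(self) -> int:
        return int(self.b0_flags.sum())


def read_volume(path: str | Path, space_tag: str = "subject") -> Volume:
    """Read a NIfTI-1 volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # pragma: no cover - nibabel error wrapping
        raise ValueError(f"cannot read {path} as NIfTI: {exc}") from exc
    return Volume(data=data, affine=np.asarray(img.affine), space_tag=space_tag)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; float32/int32 payloads round-trip bit-exactly."""
    img = nib.Nifti1Image(volume.data, volume.affine)
    nib.save(img, str(path))


def read_gradients(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read FSL-dialect bval (1 row) and bvec (3 rows x n columns) files."""
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1)
    if bvecs.shape[0] != 3:
        raise ValueError("bvec file must have 3 rows")
    if bvecs.shape[1] != bvals.size:
        raise ValueError(
            f"bval count ({bvals.size}) != bvec column count ({bvecs.shape[1]})"
        )
    return GradientTable(bvals=bvals, bvecs=bvecs.T)


def write_gradients(table: GradientTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    np.savetxt(bval_path, table.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, table.bvecs.T, fmt="%.10g")


def rotate_gradients(table: GradientTable, affine_3x3: np.ndarray) -> GradientTable:
    """Rotate gradient directions by the rotation factor of a linear map.

    The rotational part R is extracted by polar decomposition; b-values are
    unchanged and rotated directions are renormalized.
    """
    m = np.asarray(affine_3x3, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("matrix is singular")
    rot, _ = polar(m)
    bvecs = table.bvecs @ rot.T
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 0
    bvecs[nz] /= norms[nz, None]
    return GradientTable(bvals=table.bvals.copy(), bvecs=bvecs)


def resample(volume: Volume, target: Volume | BinaryMask, method: str = "tricubic") -> Volume:
    """Resample a volume onto another grid.

    ``method='tricubic'`` uses a cubic spline with mirror boundaries;
    ``method='nearest'`` preserves the input value set (labels stay labels).
    """
    if method not in ("tricubic", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    tgt_affine = np.asarray(target.affine, dtype=float)
    if abs(np.linalg.det(tgt_affine[:3, :3])) < 1e-12:
        raise ValueError("degenerate target affine")
    tgt_shape = tuple(np.asarray(target.data.shape[:3]))
    # target voxel -> world -> source voxel
    mapping = np.linalg.inv(volume.affine) @ tgt_affine
    grid = np.indices(tgt_shape, dtype=float).reshape(3, -1)
    coords = mapping[:3, :3] @ grid + mapping[:3, 3:4]
    order = 3 if method == "tricubic" else 0
    if volume.data.ndim == 3:
        out = ndimage.map_coordinates(
            volume.data.astype(float), coords, order=order, mode="mirror"
        ).reshape(tgt_shape)
    else:
        out = np.stack(
            [
                ndimage.map_coordinates(
                    volume.data[..., c].astype(float), coords, order=order, mode="mirror"
                ).reshape(tgt_shape)
                for c in range(volume.data.shape[3])
            ],
            axis=-1,
        )
    if method == "nearest":
        out = out.astype(volume.data.dtype)
    return Volume(data=out, affine=tgt_affine, space_tag=getattr(target, "space_tag", volume.space_tag))
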