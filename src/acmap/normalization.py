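"""Tensor-field spatial normalization: deformation fields, PPD reorientation,
Jacobian determinants and atrophy covariates.

A :class:`DeformationField` stores, per atlas voxel, the displacement (mm)
from the atlas-space position to the corresponding subject-space position
(pull-back convention).  Warping a subject tensor field therefore samples
model parameters at the mapped position and reorients each component tensor
with the local linear map of the subject->atlas direction, i.e. the inverse
of the field's local affine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BinaryMask, Volume
from .multitensor import TensorField

log = logging.getLogger(__name__)


@dataclass
class DeformationField:
    """Atlas->subject displacement field on the atlas grid."""

    displacement: np.ndarray  # (X,Y,Z,3) mm
    affine: np.ndarray  # atlas voxel -> world

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError("displacement must be (X,Y,Z,3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.displacement.shape[:3])

    def map_voxels(self, idx: np.ndarray) -> np.ndarray:
        """World (mm) subject positions for integer atlas voxel indices (n,3)."""
        idx = np.atleast_2d(idx)
        world = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return world + self.displacement[idx[:, 0], idx[:, 1], idx[:, 2]]

    def local_affines(self, idx: np.ndarray) -> np.ndarray:
        """Local linear maps F = d(subject pos)/d(atlas pos) at voxels (n,3).

        Central finite differences at voxel spacing; one-sided at the grid
        boundary.
        """
        idx = np.atleast_2d(idx)
        grads = _displacement_gradients(self.displacement, self.affine)
        f = grads[idx[:, 0], idx[:, 1], idx[:, 2]]
        return f

    def local_affine(self, idx: tuple[int, int, int]) -> np.ndarray:
        return self.local_affines(np.asarray(idx)[None, :])[0]


def _displacement_gradients(disp: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """(X,Y,Z,3,3) array of F = I + du/dx (du/dx in world coordinates)."""
    a3_inv = np.linalg.inv(affine[:3, :3])
    # du/dv: derivative of each displacement component wrt voxel index
    dudv = np.stack(
        [np.stack(np.gradient(disp[..., c]), axis=-1) for c in range(3)], axis=-2
    )  # (X,Y,Z, comp, voxel-axis)
    dudx = dudv @ a3_inv  # chain rule voxel -> world
    return np.eye(3) + dudx


def local_affine(deformation: DeformationField, atlas_voxel: tuple[int, int, int]) -> np.ndarray:
    """Local affine at one atlas voxel; error on the grid boundary."""
    idx = np.asarray(atlas_voxel, dtype=int)
    shape = np.asarray(deformation.shape)
    if np.any(idx < 1) or np.any(idx > shape - 2):
        raise ValueError("position on grid boundary; no central stencil")
    return deformation.local_affine(tuple(idx))


def ppd_reorient(tensor_matrix: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Preservation-of-principal-direction reorientation of one tensor.

    The principal axis maps through ``f`` and is renormalized; the secondary
    axis is the orthogonalized image of e2; eigenvalues are untouched, so FA
    and MD are invariant.
    """
    out = ppd_reorient_many(np.asarray(tensor_matrix, float)[None], np.asarray(f, float)[None])
    return out[0]


def ppd_reorient_many(tensors: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Vectorized PPD: ``tensors`` (n,3,3) symmetric, ``f`` (n,3,3) invertible."""
    dets = np.linalg.det(f)
    if np.any(np.abs(dets) < 1e-12):
        raise ValueError("singular local affine")
    w, v = np.linalg.eigh(tensors)  # ascending
    e1 = v[..., 2]
    e2 = v[..., 1]
    n1 = np.einsum("nij,nj->ni", f, e1)
    norms1 = np.linalg.norm(n1, axis=-1, keepdims=True)
    if np.any(norms1 < 1e-15):
        raise ValueError("principal axis maps to zero")
    n1 = n1 / norms1
    fe2 = np.einsum("nij,nj->ni", f, e2)
    fe2 = fe2 - np.sum(fe2 * n1, axis=-1, keepdims=True) * n1
    norms2 = np.linalg.norm(fe2, axis=-1, keepdims=True)
    # degenerate secondary image: fall back to any vector orthogonal to n1
    bad = norms2[:, 0] < 1e-12
    if np.any(bad):
        helper = np.where(np.abs(n1[bad, 0:1]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
        alt = np.cross(n1[bad], helper)
        fe2[bad] = alt
        norms2 = np.linalg.norm(fe2, axis=-1, keepdims=True)
    n2 = fe2 / norms2
    n3 = np.cross(n1, n2)
    frame = np.stack([n1, n2, n3], axis=-1)  # columns
    lam = w[..., ::-1]  # descending, matched to (n1, n2, n3)
    return np.einsum("nik,nk,njk->nij", frame, lam, frame)


def warp_tensor_field(
    field: TensorField, deformation: DeformationField, atlas_mask: BinaryMask
) -> TensorField:
    """Pull a subject-space tensor field onto the atlas grid with PPD.

    Model parameters are looked up nearest-neighbour at the mapped position
    (no interpolation across voxels with differing fiber counts); every
    component tensor is PPD-reoriented with the inverse local affine, so the
    tensors carry subject orientations into atlas space.  Atlas voxels whose
    mapped position falls outside the subject grid become background.
    """
    out = TensorField.empty(tuple(atlas_mask.data.shape), atlas_mask.affine, "atlas")
    idx = atlas_mask.indices()
    if len(idx) == 0:
        return out
    subj_world = deformation.map_voxels(idx)
    inv = np.linalg.inv(field.affine)
    subj_vox = np.rint(subj_world @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = np.asarray(field.shape)
    inside = np.all((subj_vox >= 0) & (subj_vox < shape), axis=1)
    if not np.all(inside):
        log.warning("%d atlas voxels map outside the subject grid", int((~inside).sum()))
    if not np.any(inside):
        return out
    idx = idx[inside]
    subj_vox = subj_vox[inside]
    nfib = field.n_fibers[subj_vox[:, 0], subj_vox[:, 1], subj_vox[:, 2]]
    keep = nfib > 0
    idx, subj_vox, nfib = idx[keep], subj_vox[keep], nfib[keep]
    if len(idx) == 0:
        return out
    f_local = deformation.local_affines(idx)
    g = np.linalg.inv(f_local)  # subject -> atlas linear map
    for comp in range(2):
        has = nfib > comp
        if not np.any(has):
            continue
        src = subj_vox[has]
        mats = field.tensors[src[:, 0], src[:, 1], src[:, 2], comp]
        rotated = ppd_reorient_many(mats, g[has])
        dst = idx[has]
        out.tensors[dst[:, 0], dst[:, 1], dst[:, 2], comp] = rotated
    out.n_fibers[idx[:, 0], idx[:, 1], idx[:, 2]] = nfib
    out.fractions[idx[:, 0], idx[:, 1], idx[:, 2]] = field.fractions[
        subj_vox[:, 0], subj_vox[:, 1], subj_vox[:, 2]
    ]
    out.s0[idx[:, 0], idx[:, 1], idx[:, 2]] = field.s0[
        subj_vox[:, 0], subj_vox[:, 1], subj_vox[:, 2]
    ]
    return out


def jacobian_map(deformation: DeformationField) -> Volume:
    """det(local affine) per atlas voxel; >1 where subject tissue is larger."""
    grads = _displacement_gradients(deformation.displacement, deformation.affine)
    return Volume(np.linalg.det(grads), deformation.affine, "atlas")


def atrophy_covariate(
    wm_mask: BinaryMask, deformation: DeformationField, icv: float
) -> Volume:
    """Jacobian-modulated WM mask scaled by 1/ICV (mm^3)."""
    if icv <= 0:
        raise ValueError("icv must be positive")
    detj = jacobian_map(deformation).data
    return Volume(wm_mask.data * detj / icv, deformation.affine, "atlas")


# -- analytic field constructors (download-free test geometry) ---------------


def identity_field(shape: tuple[int, int, int], affine: np.ndarray) -> DeformationField:
    return DeformationField(np.zeros(tuple(shape) + (3,)), affine)


def affine_field(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    matrix: np.ndarray,
    center: np.ndarray | None = None,
) -> DeformationField:
    """Field whose mapping is the world-space affine x -> M (x - c) + c."""
    affine = np.asarray(affine, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if center is None:
        center = (np.asarray(shape, float) - 1) / 2 @ affine[:3, :3].T + affine[:3, 3]
    grid = np.indices(shape, dtype=float)
    world = np.einsum("ij,j...->i...", affine[:3, :3], grid) + affine[:3, 3, None, None, None]
    world = np.moveaxis(world, 0, -1)
    mapped = (world - center) @ matrix.T + center
    return DeformationField(mapped - world, affine)


def rotation_field(
    shape: tuple[int, int, int], affine: np.ndarray, rotation: np.ndarray,
    center: np.ndarray | None = None,
) -> DeformationField:
    """Pull-back field that rotates image content by ``rotation``.

    The atlas position x samples the subject at R^-1 (x - c) + c, so warped
    content (and PPD-reoriented tensors) appear rotated by R.
    """
    rotation = np.asarray(rotation, dtype=float)
    return affine_field(shape, affine, rotation.T, center)


def radial_bump_field(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    amplitude: float,
    sigma_mm: float,
    center: np.ndarray | None = None,
) -> DeformationField:
    """Smooth radial expansion u(x) = a * (x-c) * exp(-|x-c|^2 / 2 sigma^2)."""
    affine = np.asarray(affine, dtype=float)
    if center is None:
        center = (np.asarray(shape, float) - 1) / 2 @ affine[:3, :3].T + affine[:3, 3]
    grid = np.indices(shape, dtype=float)
    world = np.einsum("ij,j...->i...", affine[:3, :3], grid) + affine[:3, 3, None, None, None]
    world = np.moveaxis(world, 0, -1)
    rel = world - center
    r2 = np.sum(rel**2, axis=-1, keepdims=True)
    disp = amplitude * rel * np.exp(-r2 / (2 * sigma_mm**2))
    return DeformationField(disp, affine)
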