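"""Synthetic fiber phantoms and patient-like cohorts.

Phantoms carry known tensor geometry (straight tube, 90-degree crossing,
curved arc) so fitting, warping, tracking and counting can all be checked
against closed-form truth.  Cohorts emulate a three-group study (healthy /
RR-like / SP-like): patients get focal "lesions" — eigenvalue blends toward
the equal-trace isotropic tensor, which lowers FA at roughly constant MD —
and a disability score linearly coupled to total tract damage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BinaryMask, GradientTable, Volume
from .multitensor import DiffusionTensor, TensorField

DEFAULT_EVALS = np.array([1.7e-3, 0.3e-3, 0.3e-3])  # prolate WM-like tensor
DEFAULT_BACKGROUND_D = 0.7e-3


# -- gradient scheme ----------------------------------------------------------


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, well-spread unit directions on a hemisphere."""
    golden = (1 + np.sqrt(5)) / 2
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere only (antipodal symmetry)
    phi = 2 * np.pi * i / golden
    s = np.sqrt(1 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def default_scheme(n_b0: int = 10, n_dirs: int = 61, bval: float = 1200.0) -> GradientTable:
    """Reference single-shell acquisition (10 b0 + 61 directions
    at b = 1200 s/mm^2) with a deterministic spiral direction set."""
    dirs = _fibonacci_hemisphere(n_dirs)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, bval)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


# -- phantom geometry ---------------------------------------------------------


@dataclass
class PhantomSpec:
    geometry: str = "straight_tube"  # straight_tube | crossing | curved_arc
    dims: tuple[int, int, int] = (24, 16, 16)
    radius: float = 2.0  # voxels
    fiber_evals: np.ndarray = field(default_factory=lambda: DEFAULT_EVALS.copy())
    background_d: float = DEFAULT_BACKGROUND_D
    include_background: bool = False
    s0: float = 1.0
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        self.fiber_evals = np.asarray(self.fiber_evals, float)
        if np.any(self.fiber_evals <= 0):
            raise ValueError("fiber eigenvalues must be positive")
        if self.geometry not in ("straight_tube", "crossing", "curved_arc"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.radius >= min(self.dims[1:]) / 2:
            raise ValueError("tube does not fit inside the grid")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size_mm
        return a


def _tube_masks_and_tangents(spec: PhantomSpec):
    """Per geometry: list of (mask, tangent-field) bundles."""
    nx, ny, nz = spec.dims
    ii, jj, kk = np.indices(spec.dims, dtype=float)
    cy, cz = (ny - 1) / 2, (nz - 1) / 2
    cx = (nx - 1) / 2
    bundles = []
    if spec.geometry in ("straight_tube", "crossing"):
        in_x = (jj - cy) ** 2 + (kk - cz) ** 2 <= spec.radius**2
        tan_x = np.zeros(spec.dims + (3,))
        tan_x[..., 0] = 1.0
        bundles.append((in_x, tan_x))
    if spec.geometry == "crossing":
        in_y = (ii - cx) ** 2 + (kk - cz) ** 2 <= spec.radius**2
        tan_y = np.zeros(spec.dims + (3,))
        tan_y[..., 1] = 1.0
        bundles.append((in_y, tan_y))
    if spec.geometry == "curved_arc":
        arc_r = 0.7 * min(nx, ny)
        rad = np.sqrt(ii**2 + jj**2)
        in_arc = (np.abs(rad - arc_r) <= spec.radius) & (np.abs(kk - cz) <= spec.radius)
        tan = np.zeros(spec.dims + (3,))
        norm = np.maximum(rad, 1e-9)
        tan[..., 0] = -jj / norm
        tan[..., 1] = ii / norm
        bundles.append((in_arc, tan))
    return bundles


def make_tensor_phantom(spec: PhantomSpec) -> tuple[TensorField, BinaryMask]:
    """Build the phantom tensor field and its tube mask.

    In-tube voxels carry a prolate tensor aligned with the local tract
    tangent; crossing-overlap voxels carry two tensors at weight 1/2; with
    ``include_background`` the rest of the grid gets an isotropic tensor.
    """
    bundles = _tube_masks_and_tangents(spec)
    tf = TensorField.empty(spec.dims, spec.affine)
    any_tube = np.zeros(spec.dims, dtype=bool)
    for mask, tangents in bundles:
        any_tube |= mask
        for i, j, k in np.argwhere(mask):
            tangent = tangents[i, j, k]
            tensor = DiffusionTensor.from_evals(spec.fiber_evals, tangent)
            comp = int(tf.n_fibers[i, j, k])
            if comp >= 2:
                continue
            tf.tensors[i, j, k, comp] = tensor.matrix
            tf.fractions[i, j, k, comp] = 1.0
            tf.n_fibers[i, j, k] = comp + 1
            tf.s0[i, j, k] = spec.s0
    multi = tf.n_fibers == 2
    tf.fractions[multi] = 0.5
    if spec.include_background:
        bg = ~any_tube
        iso = np.eye(3) * spec.background_d
        tf.tensors[bg, 0] = iso
        tf.fractions[bg, 0] = 1.0
        tf.n_fibers[bg] = 1
        tf.s0[bg] = spec.s0
    tube_mask = BinaryMask(any_tube.astype(np.uint8), spec.affine)
    return tf, tube_mask


# -- DWI simulation -----------------------------------------------------------


def simulate_dwi(
    tensor_field: TensorField,
    table: GradientTable,
    snr: float = np.inf,
    rng: np.random.Generator | int | None = None,
) -> Volume:
    """Simulate a 4D DWI volume from a tensor field.

    Noise-free signals follow the mixture model; finite ``snr`` adds Rician
    noise with sigma = S0/snr per voxel.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shape = tensor_field.shape
    n_meas = len(table)
    data = np.zeros(shape + (n_meas,))
    idx = tensor_field.mask.indices()
    if len(idx):
        nfib = tensor_field.n_fibers[idx[:, 0], idx[:, 1], idx[:, 2]]
        s0 = tensor_field.s0[idx[:, 0], idx[:, 1], idx[:, 2]]
        fr = tensor_field.fractions[idx[:, 0], idx[:, 1], idx[:, 2]]
        sig = np.zeros((len(idx), n_meas))
        for comp in range(2):
            has = nfib > comp
            if not np.any(has):
                continue
            mats = tensor_field.tensors[idx[has, 0], idx[has, 1], idx[has, 2], comp]
            quad = np.einsum("mi,nij,mj->nm", table.bvecs, mats, table.bvecs)
            sig[has] += fr[has, comp][:, None] * np.exp(-table.bvals[None, :] * quad)
        sig *= s0[:, None]
        if np.isfinite(snr):
            sigma = s0[:, None] / snr  # per-voxel noise floor
            sig = np.sqrt(
                (sig + rng.normal(0.0, 1.0, sig.shape) * sigma) ** 2
                + (rng.normal(0.0, 1.0, sig.shape) * sigma) ** 2
            )
        data[idx[:, 0], idx[:, 1], idx[:, 2]] = sig
    return Volume(data, tensor_field.affine, tensor_field.space_tag)


# -- cohorts ------------------------------------------------------------------

# per-group age means/SDs mimic a typical three-group MS cohort
_AGE_PARAMS = {"healthy": (44.60, 9.87), "RR": (39.45, 8.98), "SP": (49.34, 11.31)}


@dataclass
class CohortSpec:
    n_healthy: int = 20
    n_rr: int = 19
    n_sp: int = 15
    lesion_count_rr: int = 2
    lesion_count_sp: int = 4
    lesion_radius: float = 1.5  # voxels
    effect_rr: float = 0.3  # fractional blend toward isotropy
    effect_sp: float = 0.5
    edss_slope: float = 8.0  # EDSS per unit damage fraction
    edss_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for e in (self.effect_rr, self.effect_sp):
            if not 0 <= e < 1:
                raise ValueError("lesion effect must be in [0, 1)")
        if min(self.n_healthy, self.n_rr, self.n_sp) < 2:
            raise ValueError("need n >= 2 per group")


@dataclass
class Subject:
    subject_id: str
    group: str
    tensor_field: TensorField
    lesion_mask: BinaryMask
    age: float
    gender: int
    icv: float
    edss: float | None
    damage: float


def _blend_toward_isotropy(matrix: np.ndarray, effect: float) -> np.ndarray:
    iso = np.eye(3) * (np.trace(matrix) / 3.0)
    return (1 - effect) * matrix + effect * iso


def _lesion_subject(
    template: TensorField,
    tube_mask: BinaryMask,
    n_lesions: int,
    radius: float,
    effect: float,
    rng: np.random.Generator,
) -> tuple[TensorField, BinaryMask, float]:
    tf = TensorField(
        n_fibers=template.n_fibers.copy(),
        tensors=template.tensors.copy(),
        fractions=template.fractions.copy(),
        s0=template.s0.copy(),
        affine=template.affine.copy(),
        space_tag=template.space_tag,
    )
    lesion = np.zeros(template.shape, dtype=np.uint8)
    tube_idx = tube_mask.indices()
    grid = np.indices(template.shape, dtype=float)
    for _ in range(n_lesions):
        center = tube_idx[rng.integers(len(tube_idx))]
        dist2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
        lesion |= (dist2 <= radius**2).astype(np.uint8)
    lesion &= tube_mask.data
    for i, j, k in np.argwhere(lesion):
        for comp in range(int(tf.n_fibers[i, j, k])):
            tf.tensors[i, j, k, comp] = _blend_toward_isotropy(
                tf.tensors[i, j, k, comp], effect
            )
    damage = effect * lesion.sum() / max(tube_mask.n_voxels, 1)
    return tf, BinaryMask(lesion, template.affine, template.space_tag), damage


def make_cohort(
    cohort_spec: CohortSpec, phantom_spec: PhantomSpec | None = None
) -> list[Subject]:
    """Generate a three-group cohort of lesioned phantom subjects.

    Healthy subjects get the clean template (EDSS absent); RR-like and
    SP-like subjects get increasing lesion number/effect, with EDSS =
    slope * damage + Gaussian noise, clipped to [0, 10].
    """
    phantom_spec = phantom_spec or PhantomSpec()
    rng = np.random.default_rng(cohort_spec.seed)
    template, tube_mask = make_tensor_phantom(phantom_spec)
    groups = (
        [("healthy", 0, 0.0)] * cohort_spec.n_healthy
        + [("RR", cohort_spec.lesion_count_rr, cohort_spec.effect_rr)] * cohort_spec.n_rr
        + [("SP", cohort_spec.lesion_count_sp, cohort_spec.effect_sp)] * cohort_spec.n_sp
    )
    subjects = []
    for sid, (group, n_les, effect) in enumerate(groups):
        if n_les > 0 and effect > 0:
            tf, lesion, damage = _lesion_subject(
                template, tube_mask, n_les, cohort_spec.lesion_radius, effect, rng
            )
        else:
            tf = template
            lesion = BinaryMask(
                np.zeros(template.shape, dtype=np.uint8), template.affine
            )
            damage = 0.0
        mu, sd = _AGE_PARAMS[group]
        age = float(rng.normal(mu, sd))
        gender = int(rng.random() < 0.5)
        icv = float(rng.normal(1.5e6, 1.0e5))
        edss = None
        if group != "healthy":
            edss = float(
                np.clip(
                    cohort_spec.edss_slope * damage
                    + rng.normal(0, cohort_spec.edss_noise_sd),
                    0.0,
                    10.0,
                )
            )
        subjects.append(
            Subject(
                subject_id=f"sub-{sid:03d}",
                group=group,
                tensor_field=tf,
                lesion_mask=lesion,
                age=age,
                gender=gender,
                icv=icv,
                edss=edss,
                damage=damage,
            )
        )
    return subjects


def cohort_design_table(subjects: list[Subject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "gender": [s.gender for s in subjects],
            "icv": [s.icv for s in subjects],
            "edss": [s.edss if s.edss is not None else np.nan for s in subjects],
        }
    )
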