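"""Per-voxel single- and two-tensor diffusion model fitting and scalar maps.

The signal model is a volume-fraction mixture of Gaussian tensors,

    S(g, b) = S0 * sum_i f_i * exp(-b g^T D_i g),

fitted by log-linear least squares (single tensor) followed by
Levenberg-Marquardt refinement with a Cholesky-factor parameterization so
every fitted tensor is positive semi-definite.  Volume fractions are kept
on the simplex with a logistic transform.  Model order (1 vs 2 fibers) is
decided by a nested-model F-test on residual sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io import BinaryMask, GradientTable

#: Convergence settings for the nonlinear refinement.
MAX_ITER = 200
RSS_TOL = 1e-10

#: Free parameters of each model (used by the nested F-test).
_P_SINGLE = 7  # 6 tensor components + S0
_P_TWO = 14  # 2 x 6 components + fraction + S0


@dataclass
class DiffusionTensor:
    """Symmetric 3x3 diffusion tensor (mm^2/s) with sorted eigensystem."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("tensor must be symmetric")

    @property
    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues descending and matching unit eigenvectors (columns)."""
        w, v = np.linalg.eigh(self.matrix)
        order = np.argsort(w)[::-1]
        return w[order], v[:, order]

    @property
    def evals(self) -> np.ndarray:
        return self.eigensystem[0]

    @property
    def e1(self) -> np.ndarray:
        return self.eigensystem[1][:, 0]

    @classmethod
    def from_evals(
        cls, evals: np.ndarray, e1: np.ndarray | None = None
    ) -> "DiffusionTensor":
        """Build a tensor with given eigenvalues, principal axis ``e1``."""
        evals = np.asarray(evals, dtype=float)
        if e1 is None:
            frame = np.eye(3)
        else:
            e1 = np.asarray(e1, dtype=float)
            e1 = e1 / np.linalg.norm(e1)
            helper = np.array([0.0, 0.0, 1.0])
            if abs(e1 @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            e2 = np.cross(e1, helper)
            e2 /= np.linalg.norm(e2)
            e3 = np.cross(e1, e2)
            frame = np.column_stack([e1, e2, e3])
        return cls(frame @ np.diag(evals) @ frame.T)


@dataclass
class MultiTensorVoxel:
    """1- or 2-tensor voxel model with volume fractions summing to one."""

    tensors: list[DiffusionTensor]
    fractions: np.ndarray
    s0: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.tensors) != len(self.fractions):
            raise ValueError("tensors/fractions length mismatch")
        if len(self.tensors) not in (1, 2):
            raise ValueError("only 1 or 2 tensors supported")
        if np.any(self.fractions < -1e-12):
            raise ValueError("fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def n_fibers(self) -> int:
        return len(self.tensors)


def predict_signal(voxel: MultiTensorVoxel, bval: float, bvec: np.ndarray) -> float:
    """Evaluate the mixture signal model for one gradient entry."""
    if bval < 0:
        raise ValueError("negative b-value")
    g = np.asarray(bvec, dtype=float)
    sig = 0.0
    for tensor, f in zip(voxel.tensors, voxel.fractions):
        sig += f * np.exp(-bval * (g @ tensor.matrix @ g))
    return voxel.s0 * sig


def predict_signals(voxel: MultiTensorVoxel, table: GradientTable) -> np.ndarray:
    """Vectorized :func:`predict_signal` over a gradient table."""
    quad = np.zeros(len(table))
    out = np.zeros(len(table))
    for tensor, f in zip(voxel.tensors, voxel.fractions):
        quad = np.einsum("ni,ij,nj->n", table.bvecs, tensor.matrix, table.bvecs)
        out += f * np.exp(-table.bvals * quad)
    return voxel.s0 * out


# -- parameter packing -------------------------------------------------------

_TRIL = np.tril_indices(3)


def _chol_to_tensor(params6: np.ndarray) -> np.ndarray:
    low = np.zeros((3, 3))
    low[_TRIL] = params6
    return low @ low.T


def _tensor_to_chol(matrix: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(matrix)
    w = np.clip(w, 1e-10, None)  # nudge to PD so Cholesky exists
    low = np.linalg.cholesky(v @ np.diag(w) @ v.T)
    return low[_TRIL]


_DTI_SCALE = 1e3  # optimizer works near unity; diffusivities are ~1e-3 mm^2/s


def _design_matrix(table: GradientTable) -> np.ndarray:
    """Log-linear design for ln S = ln S0 - b g^T D g (6 comps + intercept)."""
    g = table.bvecs
    b = table.bvals
    cols = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    return np.column_stack([-b[:, None] * cols, np.ones(len(b))])


def _unpack_loglinear(coef: np.ndarray) -> tuple[np.ndarray, float]:
    dxx, dyy, dzz, dxy, dxz, dyz = coef[:6]
    mat = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    return mat, float(np.exp(coef[6]))


def loglinear_fit(signals: np.ndarray, table: GradientTable) -> tuple[np.ndarray, float]:
    """Ordinary least squares on log-signals; the classic DTI estimator.

    Returns the (possibly indefinite) tensor matrix and S0.
    """
    x = _design_matrix(table)
    coef, *_ = np.linalg.lstsq(x, np.log(np.maximum(signals, 1e-12)), rcond=None)
    return _unpack_loglinear(coef)


def _check_signals(signals: np.ndarray, table: GradientTable) -> np.ndarray:
    signals = np.asarray(signals, dtype=float)
    if len(signals) != len(table):
        raise ValueError("signal/gradient count mismatch")
    if len(signals) < 7:
        raise ValueError("need at least 7 measurements")
    if np.all(signals == 0):
        raise ValueError("all-zero signal vector")
    if np.any(signals < 0):
        raise ValueError("negative signal values")
    return signals


def fit_single_tensor(
    signals: np.ndarray, table: GradientTable
) -> tuple[DiffusionTensor, float]:
    """Fit one positive-semidefinite tensor plus S0.

    Log-linear initialization followed by Levenberg-Marquardt refinement of
    Cholesky-factor parameters.
    """
    signals = _check_signals(signals, table)
    mat, s0 = loglinear_fit(signals, table)
    x0 = np.concatenate([[np.log(max(s0, 1e-9))], _tensor_to_chol(mat) * np.sqrt(_DTI_SCALE)])

    quadcols = -_design_matrix(table)[:, :6]  # b-weighted quadratic monomials

    def residuals(params: np.ndarray) -> np.ndarray:
        d = _chol_to_tensor(params[1:] / np.sqrt(_DTI_SCALE))
        comps = np.array([d[0, 0], d[1, 1], d[2, 2], d[0, 1], d[0, 2], d[1, 2]])
        return np.exp(params[0] - quadcols @ comps) - signals

    sol = optimize.least_squares(
        residuals, x0, method="lm", xtol=RSS_TOL, ftol=RSS_TOL, max_nfev=MAX_ITER * 10
    )
    d = _chol_to_tensor(sol.x[1:] / np.sqrt(_DTI_SCALE))
    return DiffusionTensor(d), float(np.exp(sol.x[0]))


def _pack_two(t1: np.ndarray, t2: np.ndarray, frac: float, s0: float) -> np.ndarray:
    frac = np.clip(frac, 1e-4, 1 - 1e-4)
    return np.concatenate(
        [
            [np.log(max(s0, 1e-9)), np.log(frac / (1 - frac))],
            _tensor_to_chol(t1) * np.sqrt(_DTI_SCALE),
            _tensor_to_chol(t2) * np.sqrt(_DTI_SCALE),
        ]
    )


def _unpack_two(params: np.ndarray) -> MultiTensorVoxel:
    s0 = float(np.exp(params[0]))
    frac = 1.0 / (1.0 + np.exp(-params[1]))
    d1 = _chol_to_tensor(params[2:8] / np.sqrt(_DTI_SCALE))
    d2 = _chol_to_tensor(params[8:14] / np.sqrt(_DTI_SCALE))
    return MultiTensorVoxel(
        tensors=[DiffusionTensor(d1), DiffusionTensor(d2)],
        fractions=np.array([frac, 1 - frac]),
        s0=s0,
    )


def _two_tensor_residuals(params: np.ndarray, signals, quadcols) -> np.ndarray:
    s0 = np.exp(params[0])
    frac = 1.0 / (1.0 + np.exp(-params[1]))
    d1 = _chol_to_tensor(params[2:8] / np.sqrt(_DTI_SCALE))
    d2 = _chol_to_tensor(params[8:14] / np.sqrt(_DTI_SCALE))
    c1 = np.array([d1[0, 0], d1[1, 1], d1[2, 2], d1[0, 1], d1[0, 2], d1[1, 2]])
    c2 = np.array([d2[0, 0], d2[1, 1], d2[2, 2], d2[0, 1], d2[0, 2], d2[1, 2]])
    model = s0 * (frac * np.exp(-quadcols @ c1) + (1 - frac) * np.exp(-quadcols @ c2))
    return model - signals


def _strongest_residual_direction(
    signals: np.ndarray, table: GradientTable, voxel: MultiTensorVoxel
) -> np.ndarray:
    pred = predict_signals(voxel, table)
    resid = signals - pred
    weighted = ~table.b0_flags
    idx = np.argmax(resid[weighted])
    return table.bvecs[weighted][idx]


def fit_two_tensor(
    signals: np.ndarray,
    table: GradientTable,
    init_axes: tuple[np.ndarray, np.ndarray] | None = None,
) -> MultiTensorVoxel:
    """Fit a two-tensor mixture; RSS never exceeds the single-tensor fit.

    Multi-start refinement: a degenerate start at the single-tensor optimum
    guarantees the nested-RSS invariant, plus informed starts from the
    single-tensor principal axis paired with (a) the strongest-residual
    gradient direction or the supplied ``init_axes`` and (b) the secondary
    eigenvector.
    """
    signals = _check_signals(signals, table)
    single, s0 = fit_single_tensor(signals, table)
    evals, evecs = single.eigensystem
    quadcols = -_design_matrix(table)[:, :6]

    lam_long = max(evals[0], 1e-6)
    lam_perp = max((evals[1] + evals[2]) / 2.0, 1e-7)

    def prolate(axis: np.ndarray) -> np.ndarray:
        return DiffusionTensor.from_evals([lam_long, lam_perp, lam_perp], axis).matrix

    single_voxel = MultiTensorVoxel([single], np.array([1.0]), s0)
    starts = [_pack_two(single.matrix, single.matrix, 0.5, s0)]
    if init_axes is not None:
        starts.append(_pack_two(prolate(init_axes[0]), prolate(init_axes[1]), 0.5, s0))
    else:
        resid_dir = _strongest_residual_direction(signals, table, single_voxel)
        starts.append(_pack_two(prolate(evecs[:, 0]), prolate(resid_dir), 0.5, s0))
        starts.append(_pack_two(prolate(evecs[:, 0]), prolate(evecs[:, 1]), 0.5, s0))

    best = None
    best_rss = np.inf
    for x0 in starts:
        sol = optimize.least_squares(
            _two_tensor_residuals,
            x0,
            args=(signals, quadcols),
            method="lm",
            xtol=RSS_TOL,
            ftol=RSS_TOL,
            max_nfev=MAX_ITER * 20,
        )
        rss = float(np.sum(sol.fun**2))
        if rss < best_rss:
            best_rss = rss
            best = sol
    voxel = _unpack_two(best.x)
    voxel.converged = bool(best.status > 0)
    return voxel


def rss(signals: np.ndarray, predicted: np.ndarray) -> float:
    return float(np.sum((np.asarray(signals) - np.asarray(predicted)) ** 2))


def classify_fibre_count(
    signals: np.ndarray, table: GradientTable, alpha: float = 0.05
) -> int:
    """Choose 1 vs 2 fibers by a nested-model F-test on residual sums of squares."""
    signals = _check_signals(signals, table)
    single, s0 = fit_single_tensor(signals, table)
    single_voxel = MultiTensorVoxel([single], np.array([1.0]), s0)
    rss1 = rss(signals, predict_signals(single_voxel, table))
    scale = float(np.sum(signals**2))
    if rss1 <= 1e-18 * scale:  # single model already explains everything
        return 1
    two = fit_two_tensor(signals, table)
    rss2 = rss(signals, predict_signals(two, table))
    n = len(signals)
    dof2 = n - _P_TWO
    if dof2 <= 0:
        raise ValueError("too few measurements for the two-tensor F-test")
    extra = _P_TWO - _P_SINGLE
    if rss2 <= 1e-18 * scale:
        return 2
    f_stat = ((rss1 - rss2) / extra) / (rss2 / dof2)
    p = stats.f.sf(max(f_stat, 0.0), extra, dof2)
    return 2 if p < alpha else 1


def compute_fa(tensor: DiffusionTensor | np.ndarray) -> float:
    """Fractional anisotropy from tensor eigenvalues (0 for the zero tensor)."""
    evals = tensor.evals if isinstance(tensor, DiffusionTensor) else np.asarray(tensor, float)
    return float(fa_from_evals(evals[None, :])[0])


def fa_from_evals(evals: np.ndarray) -> np.ndarray:
    """Vectorized FA over an (..., 3) eigenvalue array."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - mean) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    out = np.zeros(evals.shape[:-1])
    nz = den > 0
    out[nz] = np.sqrt(1.5 * num[nz] / den[nz])
    return out


def compute_md(tensor: DiffusionTensor | np.ndarray) -> float:
    """Mean diffusivity (mm^2/s)."""
    evals = tensor.evals if isinstance(tensor, DiffusionTensor) else np.asarray(tensor, float)
    return float(np.mean(evals))


# -- voxel grids of multi-tensor models -------------------------------------


@dataclass
class TensorField:
    """Grid of multi-tensor models defined on a mask.

    Array layout (X, Y, Z leading axes): ``n_fibers`` 0 outside the mask;
    ``tensors[..., i, :, :]`` and ``fractions[..., i]`` for component i.
    """

    n_fibers: np.ndarray  # (X,Y,Z) int, 0 = background
    tensors: np.ndarray  # (X,Y,Z,2,3,3)
    fractions: np.ndarray  # (X,Y,Z,2)
    s0: np.ndarray  # (X,Y,Z)
    affine: np.ndarray
    space_tag: str = "subject"

    @classmethod
    def empty(cls, shape: tuple[int, int, int], affine: np.ndarray, space_tag: str = "subject") -> "TensorField":
        return cls(
            n_fibers=np.zeros(shape, dtype=np.int8),
            tensors=np.zeros(shape + (2, 3, 3)),
            fractions=np.zeros(shape + (2,)),
            s0=np.zeros(shape),
            affine=np.asarray(affine, dtype=float),
            space_tag=space_tag,
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.n_fibers.shape)

    @property
    def mask(self) -> BinaryMask:
        return BinaryMask((self.n_fibers > 0).astype(np.uint8), self.affine, self.space_tag)

    def set_voxel(self, idx: tuple[int, int, int], voxel: MultiTensorVoxel) -> None:
        self.n_fibers[idx] = voxel.n_fibers
        for i, (t, f) in enumerate(zip(voxel.tensors, voxel.fractions)):
            self.tensors[idx + (i,)] = t.matrix
            self.fractions[idx + (i,)] = f
        self.s0[idx] = voxel.s0

    def get_voxel(self, idx: tuple[int, int, int]) -> MultiTensorVoxel | None:
        n = int(self.n_fibers[idx])
        if n == 0:
            return None
        return MultiTensorVoxel(
            tensors=[DiffusionTensor(self.tensors[idx + (i,)]) for i in range(n)],
            fractions=self.fractions[idx][:n] / self.fractions[idx][:n].sum(),
            s0=float(self.s0[idx]),
        )

    def principal_evals_evecs(self) -> tuple[np.ndarray, np.ndarray]:
        """Batch eigensystem of the first component tensor over the mask.

        Returns eigenvalues (n, 3) descending and e1 (n, 3) for mask voxels
        in ``mask.indices()`` order.
        """
        idx = self.mask.indices()
        mats = self.tensors[idx[:, 0], idx[:, 1], idx[:, 2], 0]
        w, v = np.linalg.eigh(mats)
        return w[:, ::-1], v[:, :, 2]

    def fa_volume(self) -> np.ndarray:
        """FA of the dominant tensor per voxel (0 in background)."""
        out = np.zeros(self.shape)
        idx = self.mask.indices()
        if len(idx):
            w, _ = self.principal_evals_evecs()
            out[idx[:, 0], idx[:, 1], idx[:, 2]] = fa_from_evals(w)
        return out


def fit_tensor_field(
    dwi: np.ndarray,
    table: GradientTable,
    mask: BinaryMask,
    affine: np.ndarray,
    alpha: float = 0.05,
    max_fibers: int = 2,
) -> TensorField:
    """Fit a (1-2)-tensor model in every mask voxel of a 4D DWI array."""
    field = TensorField.empty(tuple(mask.data.shape), affine, mask.space_tag)
    for i, j, k in mask.indices():
        signals = np.asarray(dwi[i, j, k], dtype=float)
        tensor, s0 = fit_single_tensor(signals, table)
        n = 1
        if max_fibers >= 2:
            n = classify_fibre_count(signals, table, alpha=alpha)
        if n == 1:
            voxel = MultiTensorVoxel([tensor], np.array([1.0]), s0)
        else:
            voxel = fit_two_tensor(signals, table)
        field.set_voxel((int(i), int(j), int(k)), voxel)
    return field


# -- serialization -----------------------------------------------------------

_COMP = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def tensor_field_to_array(field: TensorField) -> np.ndarray:
    """Pack a field as (X,Y,Z,16): 2x6 components, 2 fractions, n_fibers, s0."""
    shape = field.shape
    out = np.zeros(shape + (16,), dtype=np.float32)
    for comp_i in range(2):
        for c, (a, b) in enumerate(_COMP):
            out[..., comp_i * 6 + c] = field.tensors[..., comp_i, a, b]
    out[..., 12:14] = field.fractions
    out[..., 14] = field.n_fibers
    out[..., 15] = field.s0
    return out


def tensor_field_from_array(arr: np.ndarray, affine: np.ndarray, space_tag: str = "subject") -> TensorField:
    shape = arr.shape[:3]
    field = TensorField.empty(shape, affine, space_tag)
    for comp_i in range(2):
        for c, (a, b) in enumerate(_COMP):
            field.tensors[..., comp_i, a, b] = arr[..., comp_i * 6 + c]
            field.tensors[..., comp_i, b, a] = arr[..., comp_i * 6 + c]
    field.fractions = arr[..., 12:14].astype(float)
    field.n_fibers = np.rint(arr[..., 14]).astype(np.int8)
    field.s0 = arr[..., 15].astype(float)
    return field
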