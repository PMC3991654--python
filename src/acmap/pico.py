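"""Bingham fiber-orientation uncertainty: fitting, sampling and Monte-Carlo
calibration of concentrations against tensor shape and signal-to-noise ratio.

The Bingham density on the unit sphere is parameterized with an orthonormal
frame (u1, u2, u3) and concentrations kappa1 <= kappa2 <= 0,

    p(x) proportional to exp(kappa1 (x.u1)^2 + kappa2 (x.u2)^2),

so the mode axis is u3 and the density is antipodally symmetric.  Kappas at
or below ``KAPPA_FLOOR`` are treated as a deterministic direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from .io import GradientTable
from .multitensor import DiffusionTensor, TensorField, predict_signals, MultiTensorVoxel

#: kappa at/below this value is treated as a delta-like lobe.
KAPPA_FLOOR = -1.0e4

#: sphere quadrature resolution (theta x phi) for Bingham moments.
_N_THETA, _N_PHI = 64, 128


@dataclass
class BinghamLobe:
    frame: np.ndarray  # columns u1, u2, u3 (mode = u3)
    kappas: np.ndarray  # (kappa1, kappa2), kappa1 <= kappa2 <= 0

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=float)
        self.kappas = np.asarray(self.kappas, dtype=float)
        if not np.allclose(self.frame.T @ self.frame, np.eye(3), atol=1e-9):
            raise ValueError("frame must be orthonormal")
        k1, k2 = self.kappas
        if not (k1 <= k2 + 1e-12 and k2 <= 1e-12):
            raise ValueError("require kappa1 <= kappa2 <= 0")

    @property
    def mode(self) -> np.ndarray:
        return self.frame[:, 2]

    @property
    def is_delta(self) -> bool:
        return bool(np.all(self.kappas <= KAPPA_FLOOR))


# -- quadrature ---------------------------------------------------------------


def _sphere_quadrature() -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre x uniform-phi nodes (n,3) and weights on S^2."""
    ct, wt = np.polynomial.legendre.leggauss(_N_THETA)
    phi = (np.arange(_N_PHI) + 0.5) * (2 * np.pi / _N_PHI)
    st = np.sqrt(1 - ct**2)
    x = st[:, None] * np.cos(phi)[None, :]
    y = st[:, None] * np.sin(phi)[None, :]
    z = np.broadcast_to(ct[:, None], x.shape)
    pts = np.stack([x, y, z], axis=-1).reshape(-1, 3)
    w = np.broadcast_to(wt[:, None] * (2 * np.pi / _N_PHI), x.shape).reshape(-1)
    return pts, w


_QUAD_PTS, _QUAD_W = _sphere_quadrature()


def bingham_moments(kappas: np.ndarray) -> np.ndarray:
    """E[(x.u1)^2], E[(x.u2)^2] under the Bingham density (canonical frame)."""
    k1, k2 = np.clip(kappas, 2 * KAPPA_FLOOR, 0.0)
    t1 = _QUAD_PTS[:, 0] ** 2
    t2 = _QUAD_PTS[:, 1] ** 2
    dens = np.exp(k1 * t1 + k2 * t2)
    z = np.sum(dens * _QUAD_W)
    if z == 0:  # underflow at extreme concentration: delta-like moments
        return np.array([0.0, 0.0])
    return np.array([np.sum(t1 * dens * _QUAD_W) / z, np.sum(t2 * dens * _QUAD_W) / z])


def fit_bingham_to_axes(axes: np.ndarray) -> BinghamLobe:
    """Moment-matched Bingham fit to a set of axes (antipodally symmetrized).

    The frame comes from the scatter-matrix eigenvectors; concentrations are
    found by inverting the moment equations with sphere quadrature.
    """
    axes = np.asarray(axes, dtype=float)
    if axes.ndim != 2 or axes.shape[1] != 3 or len(axes) < 10:
        raise ValueError("need >= 10 unit 3-vectors")
    axes = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    scatter = axes.T @ axes / len(axes)
    tau, vecs = np.linalg.eigh(scatter)  # ascending: tau1 <= tau2 <= tau3
    frame = vecs  # columns u1, u2, u3 with u3 = mode
    # right-handed frame for downstream cross products
    if np.linalg.det(frame) < 0:
        frame[:, 0] = -frame[:, 0]
    if tau[2] > 1 - 1e-9 or tau[0] < 1e-12 and tau[1] < 1e-12:
        return BinghamLobe(frame, np.array([KAPPA_FLOOR, KAPPA_FLOOR]))

    target = tau[:2]

    def objective(log_neg: np.ndarray) -> np.ndarray:
        return bingham_moments(-np.exp(log_neg)) - target

    x0 = np.log(np.clip(1.0 / (2 * np.maximum(target, 1e-6)) - 1.5, 1e-3, -KAPPA_FLOOR))
    sol = optimize.least_squares(objective, x0, method="lm", xtol=1e-12, ftol=1e-12)
    kappas = np.clip(-np.exp(sol.x), KAPPA_FLOOR, 0.0)
    kappas = np.sort(kappas)  # kappa1 <= kappa2
    return BinghamLobe(frame, kappas)


def _acg_envelope_b(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Newton solve of 1/b + 1/(b+2*a1) + 1/(b+2*a2) = 1 with b in (0, 3].

    ``a_i = -kappa_i >= 0`` are the Bingham matrix eigenvalues (third is 0).
    The root parameterizes the angular-central-Gaussian envelope of the
    exact rejection sampler of Kent, Ganz & Mardia.
    """
    b = np.full_like(a1, 1.0, dtype=float)
    for _ in range(50):
        f = 1.0 / b + 1.0 / (b + 2 * a1) + 1.0 / (b + 2 * a2) - 1.0
        df = -(1.0 / b**2 + 1.0 / (b + 2 * a1) ** 2 + 1.0 / (b + 2 * a2) ** 2)
        step = f / df
        b = np.clip(b - step, 1e-12, 3.0)
        if np.max(np.abs(step)) < 1e-12:
            break
    return b


def _sample_bingham_canonical(
    kappas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One axis per row of ``kappas`` (n, 2), in the canonical frame
    (u1, u2, u3) = identity, via ACG-envelope rejection.

    The envelope keeps acceptance high for any concentration, so a handful
    of rounds suffice even for near-delta lobes.
    """
    kappas = np.atleast_2d(kappas)
    n = len(kappas)
    a = np.zeros((n, 3))
    a[:, 0] = -kappas[:, 0]
    a[:, 1] = -kappas[:, 1]
    b = _acg_envelope_b(a[:, 0], a[:, 1])
    omega = 1.0 + 2.0 * a / b[:, None]
    log_m = -(3.0 - b) / 2.0 + 1.5 * (np.log(3.0) - np.log(b))
    out = np.empty((n, 3))
    todo = np.arange(n)
    for _ in range(1000):
        z = rng.standard_normal((len(todo), 3))
        y = z / np.sqrt(omega[todo])
        x = y / np.linalg.norm(y, axis=1, keepdims=True)
        quad_a = np.einsum("ni,ni,ni->n", x, x, a[todo])
        quad_o = np.einsum("ni,ni,ni->n", x, x, omega[todo])
        log_ratio = -quad_a + 1.5 * np.log(quad_o) - log_m[todo]
        acc = np.log(rng.random(len(todo))) < log_ratio
        out[todo[acc]] = x[acc]
        todo = todo[~acc]
        if len(todo) == 0:
            return out
    out[todo] = [0.0, 0.0, 1.0]  # pragma: no cover - rejection guard
    return out


def sample_axes(lobe: BinghamLobe, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` axes from a Bingham lobe (exact rejection sampling).

    Delta-like lobes (kappas at the floor) return the mode directly.
    """
    if lobe.is_delta:
        return np.tile(lobe.mode, (n, 1))
    local = _sample_bingham_canonical(np.tile(lobe.kappas, (n, 1)), rng)
    return local @ lobe.frame.T


def sample_axis(lobe: BinghamLobe, rng: np.random.Generator) -> np.ndarray:
    return sample_axes(lobe, rng, 1)[0]


# -- Monte-Carlo calibration --------------------------------------------------


def add_rician_noise(
    signals: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma^2)."""
    e1 = rng.normal(0.0, sigma, size=signals.shape)
    e2 = rng.normal(0.0, sigma, size=signals.shape)
    return np.sqrt((signals + e1) ** 2 + e2**2)


def _batch_loglinear_e1(signals: np.ndarray, table: GradientTable) -> np.ndarray:
    """Principal eigenvectors of log-linear tensor fits, one per row of signals."""
    from .multitensor import _design_matrix  # shared design

    x = _design_matrix(table)
    coefs = np.linalg.lstsq(x, np.log(np.maximum(signals.T, 1e-12)), rcond=None)[0]
    dxx, dyy, dzz, dxy, dxz, dyz = coefs[:6]
    mats = np.empty((signals.shape[0], 3, 3))
    mats[:, 0, 0], mats[:, 1, 1], mats[:, 2, 2] = dxx, dyy, dzz
    mats[:, 0, 1] = mats[:, 1, 0] = dxy
    mats[:, 0, 2] = mats[:, 2, 0] = dxz
    mats[:, 1, 2] = mats[:, 2, 1] = dyz
    _, vecs = np.linalg.eigh(mats)
    return vecs[:, :, 2]


def calibrate(
    tensor_eigenvalues: np.ndarray,
    snr: float,
    table: GradientTable,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    s0: float = 1.0,
) -> np.ndarray:
    """Monte-Carlo kappas for one tensor shape at one SNR.

    Per trial: noise-free signals from the tensor are Rician-corrupted with
    sigma = S0/SNR, a single tensor is refit (log-linear estimator) and its
    principal axis collected; the Bingham fit over the collected axes gives
    (kappa1, kappa2).  ``snr=inf`` short-circuits to the kappa floor.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if n_trials < 100:
        raise ValueError("need at least 100 trials")
    if np.isinf(snr):
        return np.array([KAPPA_FLOOR, KAPPA_FLOOR])
    rng = np.random.default_rng(0) if rng is None else rng
    tensor = DiffusionTensor.from_evals(tensor_eigenvalues, e1=np.array([0.0, 0.0, 1.0]))
    voxel = MultiTensorVoxel([tensor], np.array([1.0]), s0)
    clean = predict_signals(voxel, table)
    noisy = add_rician_noise(np.tile(clean, (n_trials, 1)), s0 / snr, rng)
    axes = _batch_loglinear_e1(noisy, table)
    return fit_bingham_to_axes(axes).kappas


@dataclass
class CalibrationTable:
    """(shape-ratio bins x SNR) -> (kappa1, kappa2) lookup from simulation."""

    ratio_bins: np.ndarray  # bin centers for lambda1/lambda2 and lambda2/lambda3
    snrs: np.ndarray
    kappas: np.ndarray  # (n_bins, n_bins, n_snr, 2)
    n_trials: int
    seed: int
    scheme_id: str = ""

    def lookup(self, eigenvalues: np.ndarray, snr: float) -> np.ndarray:
        """Nearest-bin kappas; raises if the SNR is not tabulated."""
        evals = np.sort(np.asarray(eigenvalues, float))[::-1]
        lam = np.maximum(evals, 1e-12)
        r1, r2 = lam[0] / lam[1], lam[1] / lam[2]
        i = int(np.argmin(np.abs(np.log(self.ratio_bins) - np.log(r1))))
        j = int(np.argmin(np.abs(np.log(self.ratio_bins) - np.log(r2))))
        s_idx = np.where(np.isclose(self.snrs, snr))[0]
        if len(s_idx) == 0:
            raise KeyError(f"snr {snr} not in calibration table")
        return self.kappas[i, j, s_idx[0]].copy()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ratio_bins": self.ratio_bins.tolist(),
            "snrs": self.snrs.tolist(),
            "kappas": self.kappas.tolist(),
            "n_trials": self.n_trials,
            "seed": self.seed,
            "scheme_id": self.scheme_id,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationTable":
        d = json.loads(Path(path).read_text())
        return cls(
            ratio_bins=np.asarray(d["ratio_bins"], float),
            snrs=np.asarray(d["snrs"], float),
            kappas=np.asarray(d["kappas"], float),
            n_trials=int(d["n_trials"]),
            seed=int(d["seed"]),
            scheme_id=d.get("scheme_id", ""),
        )


def build_calibration_table(
    table: GradientTable,
    snrs: tuple[float, ...] = (16.0,),
    ratio_bins: np.ndarray | None = None,
    n_trials: int = 1000,
    seed: int = 0,
    md: float = 0.7667e-3,
) -> CalibrationTable:
    """Simulate kappas over a grid of tensor-shape bins and SNRs.

    Eigenvalues for a (r1, r2) bin are constructed with mean diffusivity
    ``md``: lambda3 = 3 md / (r1 r2 + r2 + 1), lambda2 = r2 lambda3,
    lambda1 = r1 lambda2.
    """
    if ratio_bins is None:
        ratio_bins = np.array([1.0, 1.5, 2.5, 4.0, 6.5, 10.0])
    ratio_bins = np.asarray(ratio_bins, float)
    snrs_arr = np.asarray(snrs, float)
    kappas = np.zeros((len(ratio_bins), len(ratio_bins), len(snrs_arr), 2))
    rng = np.random.default_rng(seed)
    for i, r1 in enumerate(ratio_bins):
        for j, r2 in enumerate(ratio_bins):
            lam3 = 3 * md / (r1 * r2 + r2 + 1)
            evals = np.array([r1 * r2 * lam3, r2 * lam3, lam3])
            for k, snr in enumerate(snrs_arr):
                kappas[i, j, k] = calibrate(evals, snr, table, n_trials, rng)
    return CalibrationTable(ratio_bins, snrs_arr, kappas, n_trials, seed)


# -- fODF fields --------------------------------------------------------------


@dataclass
class FodfField:
    """Grid of 1-2 Bingham lobes per voxel (dense arrays for fast tracking)."""

    n_lobes: np.ndarray  # (X,Y,Z) int8
    frames: np.ndarray  # (X,Y,Z,2,3,3) columns u1,u2,u3
    kappas: np.ndarray  # (X,Y,Z,2,2)
    weights: np.ndarray  # (X,Y,Z,2)
    affine: np.ndarray
    space_tag: str = "atlas"

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.n_lobes.shape)

    @property
    def modes(self) -> np.ndarray:
        """(X,Y,Z,2,3) mode axes."""
        return self.frames[..., :, 2]

    @classmethod
    def empty(cls, shape: tuple[int, int, int], affine: np.ndarray, space_tag: str = "atlas") -> "FodfField":
        return cls(
            n_lobes=np.zeros(shape, dtype=np.int8),
            frames=np.zeros(tuple(shape) + (2, 3, 3)),
            kappas=np.zeros(tuple(shape) + (2, 2)),
            weights=np.zeros(tuple(shape) + (2,)),
            affine=np.asarray(affine, dtype=float),
            space_tag=space_tag,
        )


def _tensor_frames_and_evals(field: TensorField, comp: int, idx: np.ndarray):
    mats = field.tensors[idx[:, 0], idx[:, 1], idx[:, 2], comp]
    w, v = np.linalg.eigh(mats)
    return w[:, ::-1], v  # descending evals; eigh columns ascending


def build_fodf_field(
    tensor_field: TensorField,
    calibration: CalibrationTable,
    snr: float = 16.0,
) -> FodfField:
    """Per-voxel Bingham lobes: mode = tensor e1, kappas from the table,
    weights = volume fractions.

    The Bingham u1 (tightest) axis is aligned with the tensor's minor
    eigenvector and u2 with the secondary eigenvector, matching the axis
    of greatest principal-direction wobble.
    """
    out = FodfField.empty(tensor_field.shape, tensor_field.affine, tensor_field.space_tag)
    idx = tensor_field.mask.indices()
    if len(idx) == 0:
        return out
    nfib = tensor_field.n_fibers[idx[:, 0], idx[:, 1], idx[:, 2]]
    out.n_lobes[idx[:, 0], idx[:, 1], idx[:, 2]] = nfib
    fracs = tensor_field.fractions[idx[:, 0], idx[:, 1], idx[:, 2]]
    norm = np.where(nfib > 1, fracs.sum(axis=1), fracs[:, 0])
    for comp in range(2):
        has = nfib > comp
        if not np.any(has):
            continue
        sub = idx[has]
        evals, eigvecs = _tensor_frames_and_evals(tensor_field, comp, sub)
        # eigh columns ascending -> (e3, e2, e1) == (u1, u2, u3)
        frames = eigvecs.copy()
        neg = np.linalg.det(frames) < 0
        frames[neg, :, 0] = -frames[neg, :, 0]
        kaps = np.array([calibration.lookup(e, snr) for e in evals])
        out.frames[sub[:, 0], sub[:, 1], sub[:, 2], comp] = frames
        out.kappas[sub[:, 0], sub[:, 1], sub[:, 2], comp] = kaps
        out.weights[sub[:, 0], sub[:, 1], sub[:, 2], comp] = fracs[has, comp] / norm[has]
    return out


def fodf_field_to_array(field: FodfField) -> np.ndarray:
    """Pack an fODF field as (X,Y,Z,25): 2x9 frames, 2x2 kappas, 2 weights,
    n_lobes."""
    shape = field.shape
    out = np.zeros(shape + (25,), dtype=np.float64)
    out[..., 0:9] = field.frames[..., 0, :, :].reshape(shape + (9,))
    out[..., 9:18] = field.frames[..., 1, :, :].reshape(shape + (9,))
    out[..., 18:22] = field.kappas.reshape(shape + (4,))
    out[..., 22:24] = field.weights
    out[..., 24] = field.n_lobes
    return out


def fodf_field_from_array(arr: np.ndarray, affine: np.ndarray, space_tag: str = "atlas") -> FodfField:
    shape = arr.shape[:3]
    field = FodfField.empty(shape, affine, space_tag)
    field.frames[..., 0, :, :] = arr[..., 0:9].reshape(shape + (3, 3))
    field.frames[..., 1, :, :] = arr[..., 9:18].reshape(shape + (3, 3))
    field.kappas = arr[..., 18:22].reshape(shape + (2, 2)).astype(float)
    field.weights = arr[..., 22:24].astype(float)
    field.n_lobes = np.rint(arr[..., 24]).astype(np.int8)
    return field


def fodf_from_tensor_field(
    tensor_field: TensorField, kappas: np.ndarray | float = KAPPA_FLOOR
) -> FodfField:
    """fODF field with fixed kappas per lobe (delta-like by default).

    Handy for deterministic-limit tracking tests and phantoms.
    """
    if np.isscalar(kappas):
        kappas = np.array([kappas, kappas], dtype=float)
    out = FodfField.empty(tensor_field.shape, tensor_field.affine, tensor_field.space_tag)
    idx = tensor_field.mask.indices()
    if len(idx) == 0:
        return out
    nfib = tensor_field.n_fibers[idx[:, 0], idx[:, 1], idx[:, 2]]
    out.n_lobes[idx[:, 0], idx[:, 1], idx[:, 2]] = nfib
    fracs = tensor_field.fractions[idx[:, 0], idx[:, 1], idx[:, 2]]
    norm = np.where(nfib > 1, fracs.sum(axis=1), fracs[:, 0])
    for comp in range(2):
        has = nfib > comp
        if not np.any(has):
            continue
        sub = idx[has]
        _, eigvecs = _tensor_frames_and_evals(tensor_field, comp, sub)
        frames = eigvecs.copy()
        neg = np.linalg.det(frames) < 0
        frames[neg, :, 0] = -frames[neg, :, 0]
        out.frames[sub[:, 0], sub[:, 1], sub[:, 2], comp] = frames
        out.kappas[sub[:, 0], sub[:, 1], sub[:, 2], comp] = kappas
        out.weights[sub[:, 0], sub[:, 1], sub[:, 2], comp] = fracs[has, comp] / norm[has]
    return out
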