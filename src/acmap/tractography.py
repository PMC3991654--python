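"""Probabilistic streamline propagation through a Bingham fODF field.

Tracking runs in continuous voxel coordinates with a step of
``step_fraction`` voxels (default 1/10 of a voxel).  At every step the
fODF is looked up with probabilistic-nearest interpolation (one of the 8
surrounding voxels chosen with its trilinear weight), the lobe most aligned
with the current heading is selected, an axis is sampled from its Bingham
distribution and flipped into the heading hemisphere.  A streamline ends
when it exits the tracking mask, when its cumulative turning within a
single voxel exceeds the curvature limit (doubling-back guard), or at the
step cap.

The engine propagates many streamlines in lockstep (numpy-vectorized) —
:func:`propagate` is the single-seed convenience wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import BinaryMask
from .pico import KAPPA_FLOOR, FodfField

MASK_EXIT = "mask_exit"
CURVATURE = "curvature"
MAX_STEPS = "max_steps"

_REASON_CODES = {MASK_EXIT: 0, CURVATURE: 1, MAX_STEPS: 2}
_REASON_NAMES = {v: k for k, v in _REASON_CODES.items()}


@dataclass
class TrackingParams:
    step_fraction: float = 0.1
    max_steps: int = 2000
    bidirectional: bool = True
    curvature_limit_deg: float = 180.0

    def __post_init__(self) -> None:
        if not 0 < self.step_fraction <= 0.5:
            raise ValueError("step_fraction must be in (0, 0.5]")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class Streamline:
    """Polyline in continuous voxel coordinates with per-end stop reasons."""

    points: np.ndarray  # (n, 3)
    reasons: tuple[str, str]

    def __len__(self) -> int:
        return len(self.points)


class _BatchState:
    """Lockstep propagation state for M streamlines."""

    __slots__ = (
        "pos", "heading", "active", "reason", "turn", "cur_voxel",
        "visits", "points",
    )

    def __init__(self, starts: np.ndarray, headings: np.ndarray, record_points: bool):
        m = len(starts)
        self.pos = starts.astype(float).copy()
        self.heading = headings.astype(float).copy()
        self.active = np.ones(m, dtype=bool)
        self.reason = np.full(m, _REASON_CODES[MAX_STEPS], dtype=np.int8)
        self.turn = np.zeros(m)
        self.cur_voxel = np.rint(self.pos).astype(np.int64)
        self.visits: list[list[tuple[int, int, int]]] = [[] for _ in range(m)]
        self.points: list[list[np.ndarray]] | None = (
            [[p.copy()] for p in self.pos] if record_points else None
        )


def _sample_lobe_axes(
    frames: np.ndarray, kappas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Bingham sampling, one axis per (frame, kappa) row."""
    from .pico import _sample_bingham_canonical

    m = len(frames)
    out = np.empty((m, 3))
    delta = np.all(kappas <= KAPPA_FLOOR, axis=1)
    out[delta] = frames[delta][:, :, 2]
    todo = np.flatnonzero(~delta)
    if len(todo):
        local = _sample_bingham_canonical(kappas[todo], rng)
        out[todo] = np.einsum("nij,nj->ni", frames[todo], local)
    return out


def _in_mask(mask_data: np.ndarray, vox: np.ndarray) -> np.ndarray:
    shape = np.asarray(mask_data.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    res = np.zeros(len(vox), dtype=bool)
    if np.any(inside):
        v = vox[inside]
        res[inside] = mask_data[v[:, 0], v[:, 1], v[:, 2]] > 0
    return res


def _probabilistic_nearest(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pick one of the 8 surrounding voxels with its trilinear weight."""
    base = np.floor(pos).astype(np.int64)
    frac = pos - base
    pick = (rng.random(pos.shape) < frac).astype(np.int64)
    return base + pick


def fodf_at(field: FodfField, position: np.ndarray, rng: np.random.Generator):
    """Probabilistic-nearest fODF lookup at one continuous voxel position.

    Returns ``(voxel_index, n_lobes)``; ``n_lobes`` 0 means background.
    """
    pos = np.asarray(position, dtype=float)
    shape = np.asarray(field.shape)
    if np.any(pos < -0.5) or np.any(pos > shape - 0.5):
        raise ValueError("position outside field bounds")
    vox = _probabilistic_nearest(pos[None, :], rng)[0]
    vox = np.clip(vox, 0, shape - 1)
    return tuple(int(v) for v in vox), int(field.n_lobes[tuple(vox)])


def _propagate_batch(
    field: FodfField,
    mask: BinaryMask,
    starts: np.ndarray,
    headings: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
    record_points: bool = False,
) -> _BatchState:
    """Advance all streamlines until every one has terminated."""
    st = _BatchState(starts, headings, record_points)
    mask_data = mask.data
    shape = np.asarray(field.shape)
    step = params.step_fraction
    curv_limit = np.deg2rad(params.curvature_limit_deg)
    n_lobes = field.n_lobes
    for _ in range(params.max_steps):
        idx = np.flatnonzero(st.active)
        if len(idx) == 0:
            break
        pos = st.pos[idx]
        # fODF lookup: probabilistic nearest of the 8 neighbours
        vox = _probabilistic_nearest(pos, rng)
        oob = np.any((vox < 0) | (vox >= shape), axis=1)
        voxc = np.clip(vox, 0, shape - 1)
        nl = np.where(oob, 0, n_lobes[voxc[:, 0], voxc[:, 1], voxc[:, 2]])
        dead = nl == 0
        if np.any(dead):
            st.active[idx[dead]] = False
            st.reason[idx[dead]] = _REASON_CODES[MASK_EXIT]
        live = ~dead
        if not np.any(live):
            continue
        sub = idx[live]
        v = voxc[live]
        # lobe choice: max |mode . heading| among available lobes
        modes = field.frames[v[:, 0], v[:, 1], v[:, 2], :, :, 2]  # (m,2,3)
        align = np.abs(np.einsum("mlk,mk->ml", modes, st.heading[sub]))
        align[nl[live] < 2, 1] = -1.0
        lobe = np.argmax(align, axis=1)
        frames = field.frames[v[:, 0], v[:, 1], v[:, 2], lobe]
        kaps = field.kappas[v[:, 0], v[:, 1], v[:, 2], lobe]
        axis = _sample_lobe_axes(frames, kaps, rng)
        # orient into the hemisphere of the current heading
        flip = np.einsum("mi,mi->m", axis, st.heading[sub]) < 0
        axis[flip] = -axis[flip]
        # curvature bookkeeping: accumulate turning while inside one voxel
        cosang = np.clip(np.einsum("mi,mi->m", axis, st.heading[sub]), -1.0, 1.0)
        new_pos = st.pos[sub] + step * axis
        new_vox = np.rint(new_pos).astype(np.int64)
        same = np.all(new_vox == st.cur_voxel[sub], axis=1)
        st.turn[sub] = np.where(same, st.turn[sub] + np.arccos(cosang), 0.0)
        over = st.turn[sub] > curv_limit
        if np.any(over):
            stop = sub[over]
            st.active[stop] = False
            st.reason[stop] = _REASON_CODES[CURVATURE]
        go = sub[~over]
        if len(go) == 0:
            continue
        nv = new_vox[~over]
        exited = ~_in_mask(mask_data, nv)
        if np.any(exited):
            stop = go[exited]
            st.active[stop] = False
            st.reason[stop] = _REASON_CODES[MASK_EXIT]
        adv = go[~exited]
        if len(adv) == 0:
            continue
        st.pos[adv] = new_pos[~over][~exited]
        st.heading[adv] = axis[~over][~exited]
        changed = np.any(nv[~exited] != st.cur_voxel[adv], axis=1)
        st.cur_voxel[adv] = nv[~exited]
        for s, voxel in zip(adv[changed], nv[~exited][changed]):
            st.visits[s].append((int(voxel[0]), int(voxel[1]), int(voxel[2])))
        if st.points is not None:
            for s, p in zip(adv, st.pos[adv]):
                st.points[s].append(p.copy())
    return st


def _initial_axes(
    field: FodfField, seeds: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Seed-point direction: lobe chosen by weight, axis sampled from it."""
    m = len(seeds)
    nl = field.n_lobes[seeds[:, 0], seeds[:, 1], seeds[:, 2]]
    w = field.weights[seeds[:, 0], seeds[:, 1], seeds[:, 2]].copy()
    w[nl < 2, 1] = 0.0
    w0 = w[:, 0] / np.maximum(w.sum(axis=1), 1e-30)
    lobe = (rng.random(m) >= w0).astype(np.int64)
    frames = field.frames[seeds[:, 0], seeds[:, 1], seeds[:, 2], lobe]
    kaps = field.kappas[seeds[:, 0], seeds[:, 1], seeds[:, 2], lobe]
    return _sample_lobe_axes(frames, kaps, rng)


def propagate(
    seed_voxel: tuple[int, int, int],
    field: FodfField,
    mask: BinaryMask,
    params: TrackingParams,
    rng: np.random.Generator,
) -> Streamline:
    """Track a single bidirectional streamline from a seed voxel center."""
    seed = np.asarray(seed_voxel, dtype=np.int64)[None, :]
    if not _in_mask(mask.data, seed)[0]:
        raise ValueError("seed outside mask")
    if field.n_lobes[tuple(seed[0])] == 0:
        raise ValueError("seed has no fODF lobe")
    axis = _initial_axes(field, seed, rng)[0]
    start = seed.astype(float)
    dirs = np.stack([axis, -axis]) if params.bidirectional else axis[None, :]
    starts = np.repeat(start, len(dirs), axis=0)
    st = _propagate_batch(field, mask, starts, dirs, params, rng, record_points=True)
    fwd = np.asarray(st.points[0])
    if params.bidirectional:
        bwd = np.asarray(st.points[1])
        pts = np.vstack([bwd[::-1], fwd[1:]])
        reasons = (_REASON_NAMES[int(st.reason[1])], _REASON_NAMES[int(st.reason[0])])
    else:
        pts = fwd
        reasons = (MASK_EXIT, _REASON_NAMES[int(st.reason[0])])
    return Streamline(points=pts, reasons=reasons)


def propagate_visits(
    seeds: np.ndarray,
    field: FodfField,
    mask: BinaryMask,
    n_per_seed: int,
    params: TrackingParams,
    rng: np.random.Generator,
    unique: bool = True,
) -> list[np.ndarray]:
    """Voxels visited by each of ``n_per_seed`` bidirectional streamlines per
    seed; returns one (k,3) array per streamline, seed voxel included,
    ordered seed-major.  ``unique`` collapses repeat visits of one voxel by
    one streamline (``False`` keeps every voxel entry event).
    """
    seeds = np.asarray(seeds, dtype=np.int64)
    rep = np.repeat(seeds, n_per_seed, axis=0)
    axes = _initial_axes(field, rep, rng)
    starts = rep.astype(float)
    if params.bidirectional:
        st_f = _propagate_batch(field, mask, starts, axes, params, rng)
        st_b = _propagate_batch(field, mask, starts, -axes, params, rng)
        halves = (st_f.visits, st_b.visits)
    else:
        st_f = _propagate_batch(field, mask, starts, axes, params, rng)
        halves = (st_f.visits,)
    out = []
    for i in range(len(rep)):
        vox = [tuple(rep[i])]
        for h in halves:
            vox.extend(h[i])
        arr = np.asarray(vox, dtype=np.int64)
        out.append(np.unique(arr, axis=0) if unique else arr)
    return out


# -- streamline I/O -----------------------------------------------------------


def write_streamlines(streamlines: list[Streamline], path: str | Path) -> None:
    """Write streamlines; ``.trk`` (TrackVis, voxel coords stored via an
    identity-affine tractogram) or ``.tsv`` debug format by extension."""
    path = Path(path)
    if path.suffix == ".trk":
        _write_trk(streamlines, path)
        return
    lines = ["streamline\tpoint\tx\ty\tz\treason_start\treason_end"]
    for sid, s in enumerate(streamlines):
        for pid, p in enumerate(s.points):
            lines.append(
                f"{sid}\t{pid}\t{p[0]:.17g}\t{p[1]:.17g}\t{p[2]:.17g}\t{s.reasons[0]}\t{s.reasons[1]}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_streamlines(path: str | Path) -> list[Streamline]:
    path = Path(path)
    if path.suffix == ".trk":
        return _read_trk(path)
    text = path.read_text().rstrip("\n").split("\n")
    if not text or not text[0].startswith("streamline\t"):
        raise ValueError("malformed streamline TSV: missing header")
    rows: dict[int, list[tuple[int, np.ndarray, str, str]]] = {}
    for line in text[1:]:
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError("malformed streamline TSV: truncated record")
        sid, pid = int(parts[0]), int(parts[1])
        pt = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        rows.setdefault(sid, []).append((pid, pt, parts[5], parts[6]))
    out = []
    for sid in sorted(rows):
        recs = sorted(rows[sid], key=lambda r: r[0])
        pts = np.array([r[1] for r in recs])
        out.append(Streamline(points=pts, reasons=(recs[0][2], recs[0][3])))
    return out


def _write_trk(streamlines: list[Streamline], path: Path) -> None:
    import nibabel.streamlines as nibs

    tractogram = nibs.Tractogram(
        [s.points for s in streamlines],
        data_per_streamline={
            "reasons": [
                np.array(
                    [_REASON_CODES[s.reasons[0]], _REASON_CODES[s.reasons[1]]],
                    dtype=float,
                )
                for s in streamlines
            ]
        },
        affine_to_rasmm=np.eye(4),
    )
    nibs.save(tractogram, str(path))


def _read_trk(path: Path) -> list[Streamline]:
    import nibabel.streamlines as nibs

    trk = nibs.load(str(path))
    tract = trk.tractogram
    out = []
    for i, pts in enumerate(tract.streamlines):
        codes = tract.data_per_streamline["reasons"][i]
        out.append(
            Streamline(
                points=np.asarray(pts, dtype=np.float64),
                reasons=(_REASON_NAMES[int(codes[0])], _REASON_NAMES[int(codes[1])]),
            )
        )
    return out
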