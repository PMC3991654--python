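"""Anatomical connectivity maps: exhaustive seeding, streamline-visit
counting, and the precision (CV / SNR) analysis over repeated estimations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import BinaryMask, Volume
from .pico import FodfField
from .tractography import TrackingParams, propagate_visits


@dataclass
class ACMVolume:
    """Integer streamline visit counts per voxel plus provenance metadata."""

    counts: Volume
    n_per_seed: int
    seed: int | None = None
    mask_id: str = ""

    @property
    def data(self) -> np.ndarray:
        return self.counts.data


@dataclass
class PrecisionReport:
    """Mask-average CV and SNR of repeated ACM estimations per streamline count."""

    n_values: np.ndarray
    avg_cv: np.ndarray
    avg_snr: np.ndarray
    repeats: int

    def to_tsv(self, path: str | Path) -> None:
        lines = ["n_streamlines\tavg_cv\tavg_snr"]
        for n, cv, snr in zip(self.n_values, self.avg_cv, self.avg_snr):
            lines.append(f"{int(n)}\t{cv:.6g}\t{snr:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")


def compute_acm(
    fodf_field: FodfField,
    seed_mask: BinaryMask,
    n_per_seed: int,
    params: TrackingParams | None = None,
    rng: np.random.Generator | int | None = None,
    counting: str = "unique",
    chunk_streamlines: int = 4000,
) -> ACMVolume:
    """Seed ``n_per_seed`` streamlines from every mask voxel and count visits.

    ``counting='unique'`` (default) increments each distinct voxel a
    streamline traverses once; ``'per_entry'`` counts every voxel entry.
    """
    if counting not in ("unique", "per_entry"):
        raise ValueError("counting must be 'unique' or 'per_entry'")
    params = params or TrackingParams()
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seeds = seed_mask.indices()
    if len(seeds) == 0:
        raise ValueError("empty seed mask")
    if tuple(seed_mask.data.shape) != fodf_field.shape:
        raise ValueError("seed mask and fODF field grids differ")
    counts = np.zeros(fodf_field.shape, dtype=np.int32)
    per_chunk = max(1, chunk_streamlines // max(n_per_seed, 1))
    for lo in range(0, len(seeds), per_chunk):
        chunk = seeds[lo : lo + per_chunk]
        visits = propagate_visits(
            chunk, fodf_field, seed_mask, n_per_seed, params, rng,
            unique=(counting == "unique"),
        )
        for vox in visits:
            np.add.at(counts, (vox[:, 0], vox[:, 1], vox[:, 2]), 1)
    return ACMVolume(
        counts=Volume(counts, fodf_field.affine, fodf_field.space_tag),
        n_per_seed=n_per_seed,
        seed=seed,
    )


def acm_precision(
    fodf_field: FodfField,
    seed_mask: BinaryMask,
    n_values: tuple[int, ...],
    repeats: int = 5,
    params: TrackingParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> PrecisionReport:
    """Repeat ACM estimation and summarize per-voxel CV = SD/mean.

    Per streamline count N the ACM is estimated ``repeats`` times with
    independent randomness; voxels with zero mean are excluded from the CV
    average, zero-SD voxels from the SNR average.  Sample SD uses the n-1
    denominator.
    """
    if repeats < 2:
        raise ValueError("need at least 2 repeats")
    n_values = tuple(n_values)
    if list(n_values) != sorted(n_values):
        raise ValueError("n_values must be ascending")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mask_idx = seed_mask.indices()
    avg_cv = []
    avg_snr = []
    for n in n_values:
        stack = np.stack(
            [
                compute_acm(fodf_field, seed_mask, n, params, rng).data[
                    mask_idx[:, 0], mask_idx[:, 1], mask_idx[:, 2]
                ]
                for _ in range(repeats)
            ]
        ).astype(float)
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        nz = mean > 0
        avg_cv.append(float(np.mean(sd[nz] / mean[nz])))
        pos = sd > 0
        avg_snr.append(float(np.mean(mean[pos] / sd[pos])) if np.any(pos) else np.inf)
    return PrecisionReport(
        n_values=np.asarray(n_values),
        avg_cv=np.asarray(avg_cv),
        avg_snr=np.asarray(avg_snr),
        repeats=repeats,
    )
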