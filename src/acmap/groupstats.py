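"""Group-level voxel and ROI statistics.

Voxel-wise GLMs (group + age + gender + atrophy covariate) with contrast
t-maps, an unequal-variance two-sample variant on covariate-adjusted
residuals, permutation maxT small-volume FWE correction (Freedman-Lane
covariate handling), ROI medians, disability correlations with Bonferroni
adjustment, lesion frequency maps and Dice overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import BinaryMask, Volume

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


# -- smoothing ----------------------------------------------------------------


def smooth(volume: Volume, fwhm_mm: float = 4.0) -> Volume:
    """Gaussian smoothing with per-axis sigma = FWHM / (2.3548 * voxel size)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return volume.like(volume.data.copy())
    sigma = fwhm_mm / (FWHM_TO_SIGMA * volume.voxel_size)
    # reflective boundaries: constants stay constant, and image mass is
    # preserved exactly for interior-supported images
    out = ndimage.gaussian_filter(volume.data.astype(float), sigma=sigma, mode="reflect")
    return volume.like(out)


# -- study design -------------------------------------------------------------

GROUPS = ("healthy", "RR", "SP")


@dataclass
class StudyDesign:
    """Per-subject covariate table.

    ``table`` columns: subject, group (healthy|RR|SP), age, gender (0/1,
    reference 0 = male), optional edss, icv.  Group is coded as two
    indicators (RR, SP) with healthy as the reference level.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "group", "age", "gender"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StudyDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def design_matrix(self, extra: dict[str, np.ndarray] | None = None) -> tuple[np.ndarray, list[str]]:
        """Columns: intercept, RR, SP, age, gender [+ extras]."""
        t = self.table
        cols = {
            "intercept": np.ones(len(t)),
            "RR": (t["group"] == "RR").to_numpy(float),
            "SP": (t["group"] == "SP").to_numpy(float),
            "age": t["age"].to_numpy(float),
            "gender": t["gender"].to_numpy(float),
        }
        if extra:
            cols.update(extra)
        names = list(cols)
        return np.column_stack([cols[c] for c in names]), names

    def contrast(self, names: list[str], spec: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(names))
        for k, v in spec.items():
            c[names.index(k)] = v
        return c


# -- voxel-wise GLM -----------------------------------------------------------


@dataclass
class GLMResult:
    beta: np.ndarray  # (p, n_vox)
    sigma2: np.ndarray  # (n_vox,)
    t: np.ndarray  # (n_vox,)
    df: float
    fwe_p: np.ndarray | None = None
    significant: np.ndarray | None = None
    alpha: float | None = None


def _stack(per_subject_volumes: list[Volume] | np.ndarray) -> np.ndarray:
    if isinstance(per_subject_volumes, np.ndarray):
        return per_subject_volumes
    shapes = {v.data.shape for v in per_subject_volumes}
    if len(shapes) != 1:
        raise ValueError("subject volumes are not on a common grid")
    return np.stack([v.data.reshape(-1) for v in per_subject_volumes])


def _glm_t(y: np.ndarray, x: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Vectorized OLS over voxels: y (n, vox), x (n, p), contrast c (p,)."""
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient")
    if n <= p:
        raise ValueError("fewer subjects than design columns")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n - p
    sigma2 = np.sum(resid**2, axis=0) / df
    denom = np.sqrt(np.maximum(sigma2 * (c @ xtx_inv @ c), 1e-300))
    t = (c @ beta) / denom
    # numerically zero residual variance (e.g. identical subjects) -> t = 0
    scale = np.mean(y**2, axis=0)
    t[sigma2 <= 1e-24 * np.maximum(scale, 1e-300)] = 0.0
    return beta, sigma2, t, float(df)


def fit_glm(
    per_subject_volumes: list[Volume] | np.ndarray,
    design: StudyDesign | np.ndarray,
    contrast: np.ndarray | dict[str, float],
    extra_covariates: dict[str, np.ndarray] | None = None,
) -> GLMResult:
    """Voxel-wise OLS t-map for a contrast.

    ``design`` may be a :class:`StudyDesign` (contrast then given by column
    name) or a raw design matrix (contrast a vector).
    """
    y = _stack(per_subject_volumes)
    if isinstance(design, StudyDesign):
        x, names = design.design_matrix(extra_covariates)
        c = design.contrast(names, contrast) if isinstance(contrast, dict) else np.asarray(contrast, float)
    else:
        x = np.asarray(design, float)
        c = np.asarray(contrast, float)
    beta, sigma2, t, df = _glm_t(y, x, c)
    return GLMResult(beta=beta, sigma2=sigma2, t=t, df=df)


def welch_group_t(
    per_subject_volumes: list[Volume] | np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    nuisance: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Unequal-variance two-sample t per voxel (A minus B), optionally on
    residuals after regressing out nuisance covariates (intercept added)."""
    y = _stack(per_subject_volumes).astype(float)
    if nuisance is not None:
        z = np.column_stack([np.ones(len(y)), nuisance])
        y = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    a, b = y[group_a], y[group_b]
    na, nb = len(a), len(b)
    va = a.var(axis=0, ddof=1) / na
    vb = b.var(axis=0, ddof=1) / nb
    t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(np.maximum(va + vb, 1e-300))
    df = (va + vb) ** 2 / np.maximum(va**2 / (na - 1) + vb**2 / (nb - 1), 1e-300)
    return t, df


def ttest_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "pooled", tails: int = 2,
) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries; returns (t, df, p)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("negative SD")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    va, vb = sd_a**2, sd_b**2
    if va == 0 and vb == 0:
        if mean_a == mean_b:
            return 0.0, float(n_a + n_b - 2), 1.0
        raise ValueError("zero variance with unequal means")
    if variant == "pooled":
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        se = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = n_a + n_b - 2
    elif variant == "welch":
        se = np.sqrt(va / n_a + vb / n_b)
        df = (va / n_a + vb / n_b) ** 2 / (
            (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
        )
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t = (mean_a - mean_b) / se
    p = stats.t.sf(abs(t), df) * tails if tails == 2 else stats.t.sf(t, df)
    return float(t), float(df), float(p)


# -- permutation small-volume FWE ---------------------------------------------


def svc_fwe(
    per_subject_volumes: list[Volume] | np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    roi_mask: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> GLMResult:
    """Permutation maxT small-volume FWE correction for a one-tailed contrast.

    Covariates are handled with the Freedman-Lane scheme: the reduced model
    (columns with zero contrast weight) is fitted, its residuals are
    permuted and added back to the reduced fit before refitting the full
    model.  The null distribution of the maximum in-ROI t gives the
    per-voxel FWE p-values (positive-t tail; flip the contrast sign for the
    opposite direction).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if 1.0 / (n_permutations + 1) > alpha:
        raise ValueError("too few permutations for the requested alpha")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    y_full = _stack(per_subject_volumes).astype(float)
    roi_flat = np.asarray(roi_mask).reshape(-1).astype(bool)
    if roi_flat.shape[0] != y_full.shape[1]:
        raise ValueError("ROI mask does not match the volume grid")
    y = y_full[:, roi_flat]
    x = np.asarray(design, float)
    c = np.asarray(contrast, float)
    beta, sigma2, t_obs, df = _glm_t(y, x, c)

    keep = c == 0
    z = x[:, keep]
    if z.shape[1]:
        hz = z @ np.linalg.pinv(z)
        fitted = hz @ y
        resid = y - fitted
    else:
        fitted = np.zeros_like(y)
        resid = y
    n = len(y)
    max_null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(n)
        y_star = fitted + resid[perm]
        _, _, t_star, _ = _glm_t(y_star, x, c)
        max_null[i] = t_star.max()
    # rank-based FWE p with the observed map included in the null
    fwe_p = (1 + np.sum(max_null[None, :] >= t_obs[:, None], axis=1)) / (n_permutations + 1)
    res = GLMResult(beta=beta, sigma2=sigma2, t=t_obs, df=df)
    res.fwe_p = fwe_p
    res.significant = fwe_p <= alpha
    res.alpha = alpha
    return res


# -- ROI summaries and correlations -------------------------------------------


def roi_median(volume: Volume, roi_labels: np.ndarray, roi_id: int) -> float:
    """Median over in-ROI voxels (even count: midpoint of the central pair)."""
    sel = np.asarray(roi_labels) == roi_id
    if not np.any(sel):
        raise ValueError(f"ROI {roi_id} is empty")
    return float(np.median(volume.data[sel]))


@dataclass
class DisabilityCorrelation:
    pearson_r: float
    pearson_p: float
    glm_r: float
    r2: float
    pearson_p_bonferroni: float


def correlate_disability(
    medians: np.ndarray,
    edss: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    n_rois: int = 10,
) -> DisabilityCorrelation:
    """Pearson correlation of a regional median with EDSS plus a covariate-
    adjusted regression (EDSS ~ median + age + gender).

    ``glm_r`` is the fitted-vs-observed correlation of that regression and
    ``r2`` its coefficient of determination.  The Bonferroni-adjusted
    Pearson p multiplies by ``n_rois`` (capped at 1).
    """
    medians = np.asarray(medians, float)
    edss = np.asarray(edss, float)
    if len(medians) < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(medians) == 0 or np.ptp(edss) == 0:
        raise ValueError("constant input vector")
    r, p = stats.pearsonr(medians, edss)
    x = np.column_stack([np.ones(len(medians)), medians, np.asarray(age, float), np.asarray(gender, float)])
    beta = np.linalg.lstsq(x, edss, rcond=None)[0]
    fitted = x @ beta
    ss_res = np.sum((edss - fitted) ** 2)
    ss_tot = np.sum((edss - edss.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    glm_r = float(np.corrcoef(fitted, edss)[0, 1]) if np.ptp(fitted) > 0 else 0.0
    return DisabilityCorrelation(
        pearson_r=float(r),
        pearson_p=float(p),
        glm_r=glm_r,
        r2=float(r2),
        pearson_p_bonferroni=float(min(1.0, p * n_rois)),
    )


# -- lesion maps and overlap --------------------------------------------------


def _check_same_grid(masks: list[BinaryMask]) -> None:
    if not masks:
        raise ValueError("empty subject list")
    shapes = {m.data.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError("masks are not on a common grid")


def lesion_probability_map(lesion_masks: list[BinaryMask]) -> Volume:
    """Per-voxel fraction of subjects with a lesion."""
    _check_same_grid(lesion_masks)
    freq = np.mean([m.data for m in lesion_masks], axis=0)
    return Volume(freq, lesion_masks[0].affine, lesion_masks[0].space_tag)


def lesion_difference(map_a: Volume, map_b: Volume) -> Volume:
    if map_a.data.shape != map_b.data.shape:
        raise ValueError("grid mismatch")
    return map_a.like(map_a.data - map_b.data)


def proportion_test(masks_a: list[BinaryMask], masks_b: list[BinaryMask]) -> Volume:
    """Two-sample pooled t-map on per-subject binary lesion indicators."""
    _check_same_grid(masks_a + masks_b)
    a = np.stack([m.data for m in masks_a]).astype(float)
    b = np.stack([m.data for m in masks_b]).astype(float)
    na, nb = len(a), len(b)
    diff = a.mean(axis=0) - b.mean(axis=0)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    return Volume(t, masks_a[0].affine, masks_a[0].space_tag)


def dice(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); 0 when both masks are empty."""
    if mask_a.data.shape != mask_b.data.shape:
        raise ValueError("grid mismatch")
    a = mask_a.data > 0
    b = mask_b.data > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
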