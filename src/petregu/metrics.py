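"""Registration-uncertainty metrics and partial volume correction.

Overlap of a bootstrap-registered ROI with its gold-standard counterpart is
measured by the Dice coefficient

    DICE = 2 |Sr ∩ Sb| / (|Sr| + |Sb|)

(and the equivalent Jaccard index); the spread of Dice over bootstrap
replicates — summarised as its sample standard deviation per ROI and design
cell — is the registration-precision statistic.  Downstream impact on the
imaging endpoint is quantified as the coefficient of variation (CoV) of the
SUVr (target/reference uptake ratio) with and without iterative-Yang
partial volume correction.  Equality of variances between design cells is
tested with the Brown-Forsythe test (median-centred Levene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import VoxelGrid

__all__ = [
    "dice",
    "jaccard",
    "cov",
    "brown_forsythe",
    "suvr",
    "SUVrResult",
    "yang_pvc",
    "DiceDistribution",
    "UncertaintyMatrix",
    "sd_matrix",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _as_mask(m) -> np.ndarray:
    m = np.asarray(m)
    if m.dtype != bool:
        m = m.astype(bool)
    return m


def dice(sr, sb) -> float:
    """Dice overlap 2|Sr∩Sb| / (|Sr|+|Sb|); symmetric, in [0, 1]."""
    sr, sb = _as_mask(sr), _as_mask(sb)
    a, b = int(sr.sum()), int(sb.sum())
    if a + b == 0:
        raise ValueError("dice undefined for two empty masks")
    return 2.0 * int((sr & sb).sum()) / (a + b)


def jaccard(sr, sb) -> float:
    """Jaccard index |Sr∩Sb| / |Sr∪Sb|; dice = 2 j / (1 + j)."""
    sr, sb = _as_mask(sr), _as_mask(sb)
    union = int((sr | sb).sum())
    if union == 0:
        raise ValueError("jaccard undefined for two empty masks")
    return int((sr & sb).sum()) / union


def cov(values) -> float:
    """Coefficient of variation: sample SD (n-1) over the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cov requires at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("cov undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def brown_forsythe(*groups) -> tuple[float, float]:
    """Brown-Forsythe equal-variance test (ANOVA on |x - group median|).

    Accepts two or more sequences; returns (F statistic, p value).
    """
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("brown_forsythe requires at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if g.size < 3:
            raise ValueError("each group needs n >= 3")
    stat, p = stats.levene(*arrs, center="median")
    if np.isnan(stat):  # all deviations zero in every group
        return 0.0, 1.0
    return float(stat), float(p)


@dataclass(frozen=True)
class SUVrResult:
    target_roi: str
    reference_roi: str
    suvr: float
    pvc_applied: bool


def suvr(
    pet: VoxelGrid,
    labels: VoxelGrid,
    target_id: int,
    reference_id: int,
    target_name: str = "target",
    reference_name: str = "reference",
    pvc_applied: bool = False,
) -> SUVrResult:
    """Standardised uptake value ratio: mean(target) / mean(reference)."""
    lab = labels.values
    tgt = lab == target_id
    ref = lab == reference_id
    if not tgt.any():
        raise ValueError(f"target ROI {target_id} is empty")
    if not ref.any():
        raise ValueError(f"reference ROI {reference_id} is empty")
    ratio = float(pet.values[tgt].mean() / pet.values[ref].mean())
    return SUVrResult(target_name, reference_name, ratio, pvc_applied)


def yang_pvc(
    pet: VoxelGrid,
    labels: VoxelGrid,
    psf_fwhm_mm: float = 4.5,
    n_iter: int = 5,
    tol: float = 1e-4,
    region_ids=None,
) -> VoxelGrid:
    """Iterative Yang partial volume correction.

    Each iteration builds a piecewise-constant synthetic image from the
    current regional means, and corrects the PET by the voxel-wise ratio of
    the synthetic image to its PSF-smoothed version.  Requires the
    parcellation to be aligned on the PET grid.  ``psf_fwhm_mm=0`` is a
    delta PSF and returns the input unchanged.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if pet.shape != labels.shape:
        raise ValueError("labels must be aligned to the PET grid")
    if psf_fwhm_mm == 0:
        return pet.copy()

    sigma = psf_fwhm_mm * _FWHM_TO_SIGMA / np.asarray(pet.voxel_size_mm)
    lab = labels.values
    ids = np.unique(lab) if region_ids is None else np.asarray(region_ids)
    masks = [lab == i for i in ids]
    keep = []
    for i, m in zip(ids, masks):
        if m.any():
            keep.append((i, m))
        else:
            warnings.warn(f"yang_pvc: region {i} is empty and was skipped")
    masks = [m for _, m in keep]

    vals = np.asarray(pet.values, dtype=np.float64)
    corrected = vals
    prev_means = None
    for _ in range(n_iter):
        means = np.array([corrected[m].mean() for m in masks])
        synthetic = np.zeros_like(vals)
        for m, mu in zip(masks, means):
            synthetic[m] = mu
        smoothed = ndimage.gaussian_filter(synthetic, sigma, mode="constant")
        ratio = np.divide(
            synthetic, smoothed, out=np.ones_like(synthetic), where=smoothed > 1e-12
        )
        corrected = vals * ratio
        if prev_means is not None:
            denom = np.abs(prev_means).max()
            if denom > 0 and np.abs(means - prev_means).max() / denom < tol:
                break
        prev_means = means
    return pet.copy(values=np.clip(corrected, 0.0, None))


# ----------------------------------------------------------------------
# Dice distributions over the experiment design
# ----------------------------------------------------------------------
#: design-cell identity fields, in canonical order
CELL_FIELDS = ("frame", "mode", "iterations", "count_level", "engine", "voxel_mm")


@dataclass
class DiceDistribution:
    """Dice samples for one ROI in one design cell.

    ``samples`` holds the Dice coefficients of the successful bootstrap
    registrations relative to the gold-standard parcellation; replicates
    whose registration failed are excluded and counted in ``n_failed``.
    """

    roi_name: str
    frame: str
    mode: str = "AC"
    iterations: int = 2
    count_level: float = 1.0
    engine: str = "nmi-powell"
    voxel_mm: float = 2.0
    samples: np.ndarray = field(default_factory=lambda: np.array([]))
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size and (
            self.samples.min() < 0 or self.samples.max() > 1 + 1e-12
        ):
            raise ValueError("Dice samples must lie in [0, 1]")

    @property
    def sd(self) -> float:
        """Sample standard deviation (n-1 denominator)."""
        if self.samples.size < 2:
            return float("nan")
        return float(self.samples.std(ddof=1))

    @property
    def n(self) -> int:
        return int(self.samples.size)

    def cell_key(self) -> tuple:
        return (
            self.frame,
            self.mode,
            int(self.iterations),
            float(self.count_level),
            self.engine,
            float(self.voxel_mm),
        )


@dataclass
class UncertaintyMatrix:
    """Per-ROI and ROI-averaged Dice-SD tables over design cells.

    ``per_roi`` has one row per (ROI x design cell); ``averages`` one row
    per design cell with the unweighted mean SD across ROIs, a flag on the
    per-frame minimum-SD cell, and a flag on cells whose pooled Dice
    samples are statistically indistinguishable from that minimum by the
    Brown-Forsythe test at alpha = 0.05.
    """

    per_roi: pd.DataFrame
    averages: pd.DataFrame

    def to_csv(self, path_per_roi, path_averages) -> None:
        self.per_roi.to_csv(path_per_roi, index=False)
        self.averages.to_csv(path_averages, index=False)

    def to_json_dict(self) -> dict:
        return {
            "per_roi": self.per_roi.to_dict(orient="records"),
            "averages": self.averages.to_dict(orient="records"),
        }


def sd_matrix(dists, alpha: float = 0.05) -> UncertaintyMatrix:
    """Aggregate Dice distributions into SD matrices with minimum flags."""
    dists = sorted(dists, key=lambda d: (d.cell_key(), d.roi_name))
    rows = []
    cells: dict[tuple, dict] = {}
    for d in dists:
        if d.n < 2:
            warnings.warn(
                f"cell {d.cell_key()} ROI {d.roi_name}: fewer than 2 samples; reported as empty"
            )
        rows.append(
            dict(
                roi=d.roi_name,
                **dict(zip(CELL_FIELDS, d.cell_key())),
                n=d.n,
                n_failed=d.n_failed,
                sd=d.sd,
            )
        )
        c = cells.setdefault(d.cell_key(), {"sds": [], "pooled": []})
        c["sds"].append(d.sd)
        c["pooled"].append(d.samples - (d.samples.mean() if d.n else 0.0))
    per_roi = pd.DataFrame(rows)

    avg_rows = []
    for key, c in cells.items():
        avg_rows.append(
            dict(
                **dict(zip(CELL_FIELDS, key)),
                avg_sd=float(np.mean(c["sds"])),
                pooled=np.concatenate(c["pooled"]) if c["pooled"] else np.array([]),
            )
        )
    averages = pd.DataFrame(avg_rows)

    is_min = np.zeros(len(averages), dtype=bool)
    indist = np.zeros(len(averages), dtype=bool)
    for frame, grp in averages.groupby("frame"):
        i_min = grp["avg_sd"].idxmin()
        is_min[averages.index.get_loc(i_min)] = True
        ref_pool = averages.loc[i_min, "pooled"]
        for i in grp.index:
            if i == i_min:
                continue
            pool = averages.loc[i, "pooled"]
            if len(pool) >= 3 and len(ref_pool) >= 3:
                _, p = brown_forsythe(pool, ref_pool)
                if p >= alpha:
                    indist[averages.index.get_loc(i)] = True
    averages = averages.drop(columns=["pooled"])
    averages["is_min"] = is_min
    averages["indistinguishable_from_min"] = indist
    return UncertaintyMatrix(per_roi=per_roi, averages=averages)
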