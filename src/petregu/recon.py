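"""OSEM image reconstruction with switchable correction modes.

Reconstruction setups mirror the registration-input images of the
uncertainty analysis: NAC (no attenuation correction), AC (attenuation
corrected) and QNT (fully quantitative, adding scatter correction to AC).
Randoms are corrected in every mode.  The data model per sinogram bin is

    ybar_i = af_i * (A x)_i + s_i + r_i

with the additive scatter/randoms terms entering the denominator of the
multiplicative OSEM update.  A is the same matched projector used by the
simulator (including its resolution kernel), subsets are angle-interleaved,
and the initial image is uniform inside the field-of-view mask.

A 1 mm output voxel is produced by reconstructing on the native grid and
splitting each voxel into eight equal voxels, without interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid, default_affine, upsample_split
from .simulate import Sinogram, SystemModel, get_projector, _scatter_shape

__all__ = ["ReconConfig", "osem", "estimate_scatter", "poisson_loglik"]

MODES = ("NAC", "AC", "QNT")


@dataclass(frozen=True)
class ReconConfig:
    """Reconstruction mode and OSEM iteration settings."""

    mode: str = "AC"
    iterations: int = 2
    subsets: int = 14
    out_voxel_mm: float = 2.0
    native_voxel_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.subsets < 1:
            raise ValueError("subsets must be >= 1")
        if self.out_voxel_mm not in (self.native_voxel_mm, self.native_voxel_mm / 2.0):
            raise ValueError(
                "out_voxel_mm must equal the native voxel or half of it "
                "(halving is done by voxel splitting, not interpolation)"
            )


def _native_grid(sys: SystemModel, voxel_mm: float) -> VoxelGrid:
    shape = (sys.n_radial_bins, sys.n_radial_bins, sys.n_slices)
    vox = (voxel_mm, voxel_mm, voxel_mm)
    return VoxelGrid(np.zeros(shape), vox, default_affine(shape, vox))


def _fov_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Inscribed transaxial cylinder — the region the projector covers fully."""
    nx, ny, _ = shape
    ix = np.arange(nx) - (nx - 1) / 2.0
    iy = np.arange(ny) - (ny - 1) / 2.0
    r2 = ix[:, None] ** 2 + iy[None, :] ** 2
    radius = min(nx, ny) / 2.0 - 0.5
    return (r2 <= radius**2)[:, :, None] * np.ones(shape[2], dtype=bool)[None, None, :]


def osem(
    prompts: Sinogram,
    sys: SystemModel,
    cfg: ReconConfig,
    af: Sinogram | None = None,
    scatter_est: Sinogram | None = None,
    randoms_est: Sinogram | None = None,
    loglik_out: list | None = None,
) -> VoxelGrid:
    """Ordered-subsets EM reconstruction.

    ``mode='NAC'`` ignores attenuation factors and scatter, ``'AC'`` uses
    attenuation only, ``'QNT'`` uses attenuation and scatter; the randoms
    estimate is applied in every mode.  When ``loglik_out`` is a list the
    Poisson log-likelihood is appended after each full iteration.
    """
    if sys.n_angles % cfg.subsets:
        raise ValueError(
            f"n_angles={sys.n_angles} not divisible by subsets={cfg.subsets}"
        )
    y = np.asarray(prompts.values, dtype=np.float64)
    if y.shape != sys.sino_shape:
        raise ValueError("prompts shape does not match system")

    use_af = cfg.mode in ("AC", "QNT")
    use_scatter = cfg.mode == "QNT"
    if use_af and af is None:
        raise ValueError(f"mode {cfg.mode} requires attenuation factors")
    if use_scatter and scatter_est is None:
        raise ValueError("mode QNT requires a scatter estimate")

    afv = af.values if use_af else np.ones_like(y)
    add = np.zeros_like(y)
    for est in ((scatter_est,) if use_scatter else ()) + (
        (randoms_est,) if randoms_est is not None else ()
    ):
        if est is None:
            continue
        if np.any(est.values < 0):
            raise ValueError("additive estimates must be non-negative")
        add = add + est.values

    grid = _native_grid(sys, cfg.native_voxel_mm)
    proj = get_projector(grid, sys)
    fov = _fov_mask(grid.shape)

    subsets = [np.arange(k, sys.n_angles, cfg.subsets) for k in range(cfg.subsets)]
    sens = []
    for ang in subsets:
        s = proj.back(afv[ang], angles=ang)
        sens.append(np.where(s > 0, s, np.inf))  # masked division below

    x = fov.astype(np.float64)
    for _ in range(cfg.iterations):
        for ang, s in zip(subsets, sens):
            ybar = afv[ang] * proj.fwd(x, angles=ang) + add[ang]
            ratio = np.divide(y[ang], ybar, out=np.zeros_like(ybar), where=ybar > 0)
            x = x * (proj.back(afv[ang] * ratio, angles=ang) / s)
        if loglik_out is not None:
            loglik_out.append(poisson_loglik(y, afv, x, proj, add))

    out = grid.copy(values=x)
    if cfg.out_voxel_mm == cfg.native_voxel_mm / 2.0:
        out = upsample_split(out)
    return out


def poisson_loglik(
    y: np.ndarray, afv: np.ndarray, x: np.ndarray, proj, add: np.ndarray
) -> float:
    """Poisson log-likelihood sum(y log ybar - ybar) under the data model."""
    ybar = afv * proj.fwd(x) + add
    pos = ybar > 0
    ll = -ybar[pos].sum() + np.sum(y[pos] * np.log(ybar[pos]))
    return float(ll)


_TAIL_AF = 0.995


def estimate_scatter(
    prompts: Sinogram, af: Sinogram, randoms_est: Sinogram | None = None
) -> Sinogram:
    """Data-driven scatter estimate: broad blur scaled by a tail fit.

    The blurred (randoms-subtracted) prompts provide the scatter shape; the
    amplitude is fitted on tail bins whose attenuation factors are ~1, i.e.
    lines that barely intersect the object and therefore carry essentially
    no true coincidences.
    """
    residual = np.asarray(prompts.values, dtype=np.float64)
    if randoms_est is not None:
        residual = residual - randoms_est.values
    net = np.clip(residual, 0.0, None)
    template = _scatter_shape(net)
    tail = af.values >= _TAIL_AF
    t_sum = float(template[tail].sum())
    # unclipped tail sum keeps the amplitude fit unbiased under Poisson noise
    alpha = max(float(residual[tail].sum()), 0.0) / t_sum if t_sum > 0 else 0.0
    est = np.clip(alpha * template, 0.0, None)
    total_prompts = float(prompts.values.sum())
    if est.sum() > total_prompts > 0:
        est *= total_prompts / est.sum()
    return Sinogram(est, "scatter")
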