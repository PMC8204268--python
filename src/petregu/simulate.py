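"""Tomographic simulation and list-mode bootstrap resampling.

The system model is a parallel-beam, slice-stacked geometry: every sinogram
bin is a line integral through the (optionally PSF-smoothed) activity volume
in one transaxial plane.  The projector is built once as an explicit sparse
matrix per (grid, system) pair, so forward and back projection are exact
adjoints of one another — the matched-projector contract the reconstruction
relies on.

Measured data are generated per bin as Poisson draws of

    expected prompts = attenuation x trues + scatter + randoms

with scatter modelled as a broad blur of the true-coincidence sinogram and
randoms as a spatially uniform background.  Realized counts are expanded
into a randomized event list (list-mode), which is the substrate for the
nonparametric bootstrap: resampling events with replacement at a chosen
count level simulates a new measurement from the distribution represented
by the original one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .grid import VoxelGrid

__all__ = [
    "SystemModel",
    "Sinogram",
    "ListModeData",
    "default_system",
    "forward_project",
    "back_project",
    "attenuation_factors",
    "simulate_prompts",
    "bootstrap_listmode",
    "bin_events",
    "events_from_counts",
    "save_listmode",
    "load_listmode",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SINOGRAM_KINDS = ("prompts", "attenuation_factors", "scatter", "randoms", "normalization")


@dataclass(frozen=True)
class SystemModel:
    """Parallel-beam, slice-stacked scanner description.

    The radial bin width equals the in-plane PET voxel size; ``psf_fwhm_mm``
    is an isotropic Gaussian resolution kernel applied in image space before
    projection (and after back-projection, keeping the operator self-matched).
    """

    n_angles: int = 56
    n_radial_bins: int = 64
    n_slices: int = 48
    psf_fwhm_mm: float = 2.0
    geometry: str = "parallel-beam"

    def __post_init__(self) -> None:
        if self.n_angles < 8:
            raise ValueError("n_angles must be at least 8")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be non-negative")
        if self.geometry != "parallel-beam":
            raise ValueError("only parallel-beam slice-stacked geometry is supported")

    @property
    def sino_shape(self) -> tuple[int, int, int]:
        return (self.n_angles, self.n_radial_bins, self.n_slices)


def default_system(grid: VoxelGrid, n_angles: int = 56, psf_fwhm_mm: float = 2.0) -> SystemModel:
    """System model matched to a PET grid (radial bins = in-plane voxels)."""
    nx, ny, nz = grid.shape
    if nx != ny:
        raise ValueError("default system requires square in-plane grids")
    return SystemModel(n_angles=n_angles, n_radial_bins=nx, n_slices=nz, psf_fwhm_mm=psf_fwhm_mm)


@dataclass
class Sinogram:
    """Projection-space data: (n_angles, n_radial_bins, n_slices)."""

    values: np.ndarray
    kind: str = "prompts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("sinogram must be 3-D (angles, radial, slices)")
        if self.kind not in SINOGRAM_KINDS:
            raise ValueError(f"unknown sinogram kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def total(self) -> float:
        return float(self.values.sum())

    def save(self, path: str | Path) -> None:
        import json

        import nibabel as nib

        path = Path(path)
        nib.save(nib.Nifti1Image(self.values, np.eye(4)), str(path))
        sidecar = path.with_suffix("").with_suffix(".json")
        meta = {
            "kind": self.kind,
            "n_angles": self.shape[0],
            "n_radial_bins": self.shape[1],
            "n_slices": self.shape[2],
        }
        sidecar.write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Sinogram":
        import json

        import nibabel as nib

        path = Path(path)
        sidecar = path.with_suffix("").with_suffix(".json")
        kind = json.loads(sidecar.read_text())["kind"] if sidecar.exists() else "prompts"
        return cls(np.asanyarray(nib.load(str(path)).dataobj), kind)


@dataclass
class ListModeData:
    """A stream of detection events as (angle, radial, slice) bin indices."""

    events: np.ndarray
    source_frame: str = ""
    count_level: float = 1.0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int32).reshape(-1, 3)
        if not (0 < self.count_level <= 1.0 + 1e-12):
            raise ValueError("count_level must be in (0, 1]")

    @property
    def n_events(self) -> int:
        return int(self.events.shape[0])


# ----------------------------------------------------------------------
# projector construction (cached per geometry)
# ----------------------------------------------------------------------
_PROJECTOR_CACHE: dict[tuple, "_Projector"] = {}


class _Projector:
    """Sparse line-integral operator for one (grid, system) pairing."""

    def __init__(self, sys: SystemModel, nx: int, ny: int, voxel_mm: float):
        self.sys = sys
        self.nx, self.ny = nx, ny
        self.voxel_mm = voxel_mm
        self.A = self._build_matrix()
        self.sigma_vox = sys.psf_fwhm_mm * _FWHM_TO_SIGMA / voxel_mm

    def _build_matrix(self) -> sp.csr_matrix:
        sys, nx, ny, v = self.sys, self.nx, self.ny, self.voxel_mm
        n_rad = sys.n_radial_bins
        step = v / 2.0  # ray sampling step, mm
        half_x, half_y = nx * v / 2.0, ny * v / 2.0
        length = 2.0 * np.hypot(half_x, half_y)
        n_samp = int(np.ceil(length / step))
        t = (np.arange(n_samp) - (n_samp - 1) / 2.0) * step
        r_off = (np.arange(n_rad) - (n_rad - 1) / 2.0) * v

        rows_all, cols_all, data_all = [], [], []
        angles = np.pi * np.arange(sys.n_angles) / sys.n_angles
        for ia, th in enumerate(angles):
            u = np.array([np.cos(th), np.sin(th)])  # radial direction
            d = np.array([-np.sin(th), np.cos(th)])  # ray direction
            # sample positions: (n_rad, n_samp, 2) world mm
            px = r_off[:, None] * u[0] + t[None, :] * d[0]
            py = r_off[:, None] * u[1] + t[None, :] * d[1]
            # continuous voxel indices
            fx = px / v + (nx - 1) / 2.0
            fy = py / v + (ny - 1) / 2.0
            ix = np.floor(fx).astype(np.int64)
            iy = np.floor(fy).astype(np.int64)
            wx = fx - ix
            wy = fy - iy
            ray = np.broadcast_to(np.arange(n_rad, dtype=np.int64)[:, None], ix.shape)
            for dx, dy in ((0, 0), (1, 0), (0, 1), (1, 1)):
                jx, jy = ix + dx, iy + dy
                w = (wx if dx else 1 - wx) * (wy if dy else 1 - wy) * step
                ok = (jx >= 0) & (jx < nx) & (jy >= 0) & (jy < ny) & (w > 0)
                rows_all.append(ia * n_rad + ray[ok])
                cols_all.append(jx[ok] * ny + jy[ok])
                data_all.append(w[ok])
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        data = np.concatenate(data_all)
        n_rays = sys.n_angles * n_rad
        A = sp.coo_matrix((data, (rows, cols)), shape=(n_rays, nx * ny))
        return A.tocsr()

    # ------------------------------------------------------------------
    def _smooth(self, x: np.ndarray) -> np.ndarray:
        if self.sigma_vox <= 0:
            return x
        return gaussian_filter(x, self.sigma_vox, mode="constant")

    def angle_rows(self, angles: np.ndarray) -> np.ndarray:
        n_rad = self.sys.n_radial_bins
        return (np.asarray(angles)[:, None] * n_rad + np.arange(n_rad)[None, :]).ravel()

    def fwd(self, x: np.ndarray, angles: np.ndarray | None = None, psf: bool = True) -> np.ndarray:
        """Project a volume; returns (n_sel_angles, n_radial, n_slices)."""
        nz = x.shape[2]
        xs = self._smooth(x) if psf else x
        flat = xs.reshape(self.nx * self.ny, nz)
        if angles is None:
            y = self.A @ flat
            return y.reshape(self.sys.n_angles, self.sys.n_radial_bins, nz)
        rows = self.angle_rows(angles)
        y = self.A[rows] @ flat
        return y.reshape(len(angles), self.sys.n_radial_bins, nz)

    def back(self, y: np.ndarray, angles: np.ndarray | None = None, psf: bool = True) -> np.ndarray:
        """Adjoint of :meth:`fwd` (same PSF handling)."""
        nz = y.shape[-1]
        flat = y.reshape(-1, nz)
        if angles is None:
            x = self.A.T @ flat
        else:
            rows = self.angle_rows(angles)
            x = self.A[rows].T @ flat
        x = x.reshape(self.nx, self.ny, nz)
        return self._smooth(x) if psf else x


def get_projector(activity: VoxelGrid, sys: SystemModel) -> _Projector:
    nx, ny, nz = activity.shape
    vx, vy, vz = activity.voxel_size_mm
    if nx != sys.n_radial_bins or ny != sys.n_radial_bins or nz != sys.n_slices:
        raise ValueError(
            f"grid shape {activity.shape} incompatible with system "
            f"(n_radial={sys.n_radial_bins}, n_slices={sys.n_slices})"
        )
    if abs(vx - vy) > 1e-9:
        raise ValueError("in-plane voxels must be square")
    key = (sys.n_angles, sys.n_radial_bins, sys.n_slices, round(sys.psf_fwhm_mm, 9), nx, ny, round(vx, 9))
    if key not in _PROJECTOR_CACHE:
        _PROJECTOR_CACHE[key] = _Projector(sys, nx, ny, vx)
    return _PROJECTOR_CACHE[key]


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------
def forward_project(activity: VoxelGrid, sys: SystemModel, psf: bool | None = None) -> Sinogram:
    """Line integrals of the (PSF-smoothed) activity, in counts per bin."""
    if np.any(activity.values < 0):
        raise ValueError("activity must be non-negative")
    proj = get_projector(activity, sys)
    use_psf = (sys.psf_fwhm_mm > 0) if psf is None else psf
    return Sinogram(proj.fwd(np.asarray(activity.values, dtype=np.float64), psf=use_psf), "prompts")


def back_project(sino: Sinogram, grid_like: VoxelGrid, sys: SystemModel, psf: bool | None = None) -> VoxelGrid:
    """Adjoint of :func:`forward_project` onto the grid of ``grid_like``."""
    proj = get_projector(grid_like, sys)
    use_psf = (sys.psf_fwhm_mm > 0) if psf is None else psf
    return grid_like.copy(values=proj.back(sino.values, psf=use_psf))


def attenuation_factors(mu_map: VoxelGrid, sys: SystemModel) -> Sinogram:
    """Per-bin survival probabilities exp(-integral of mu along the ray).

    The attenuation line integral is geometric — no resolution kernel is
    applied to the mu-map.
    """
    if np.any(mu_map.values < 0):
        raise ValueError("mu must be non-negative")
    proj = get_projector(mu_map, sys)
    line_int = proj.fwd(np.asarray(mu_map.values, dtype=np.float64), psf=False)
    return Sinogram(np.exp(-line_int), "attenuation_factors")


_SCATTER_FWHM_BINS = 10.0  # broad kernel, well above the 5-bin floor


def _scatter_shape(trues: np.ndarray) -> np.ndarray:
    """Broad Gaussian blur of the trues over radial and axial directions."""
    sig = _SCATTER_FWHM_BINS * _FWHM_TO_SIGMA
    return gaussian_filter(trues, sigma=(0.0, sig, sig), mode="constant")


def simulate_prompts(
    activity: VoxelGrid,
    mu_map: VoxelGrid,
    sys: SystemModel,
    scatter_fraction: float = 0.15,
    randoms_fraction: float = 0.15,
    seed: int = 0,
    frame_id: str = "",
) -> tuple[ListModeData, Sinogram, Sinogram]:
    """Draw a Poisson list-mode realization of one frame.

    Returns the event list plus the *expected* scatter and randoms
    sinograms (the analogue of the scanner-side correction estimates).
    """
    if not (0 <= scatter_fraction <= 0.5 and 0 <= randoms_fraction <= 0.5):
        raise ValueError("scatter and randoms fractions must lie in [0, 0.5]")
    af = attenuation_factors(mu_map, sys)
    trues = af.values * forward_project(activity, sys).values
    t_total = trues.sum()

    frac_t = 1.0 - scatter_fraction - randoms_fraction
    total = t_total / frac_t if t_total > 0 else 0.0
    shape = _scatter_shape(trues)
    s_sum = shape.sum()
    scatter = shape * (scatter_fraction * total / s_sum) if s_sum > 0 else np.zeros_like(trues)
    randoms = np.full_like(trues, randoms_fraction * total / trues.size)

    expected = trues + scatter + randoms
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected)
    events = events_from_counts(counts, rng)
    lm = ListModeData(events, source_frame=frame_id, count_level=1.0)
    return lm, Sinogram(scatter, "scatter"), Sinogram(randoms, "randoms")


def events_from_counts(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Expand an integer sinogram into a randomly ordered event list."""
    counts = np.asarray(counts)
    flat = counts.ravel()
    idx = np.repeat(np.arange(flat.size, dtype=np.int64), flat)
    rng.shuffle(idx)
    a, rem = np.divmod(idx, counts.shape[1] * counts.shape[2])
    r, s = np.divmod(rem, counts.shape[2])
    return np.stack([a, r, s], axis=1).astype(np.int32)


def bin_events(lm: ListModeData, sys: SystemModel) -> Sinogram:
    """Histogram a list-mode stream back into an integer prompts sinogram."""
    shape = sys.sino_shape
    flat = (
        lm.events[:, 0].astype(np.int64) * shape[1] * shape[2]
        + lm.events[:, 1].astype(np.int64) * shape[2]
        + lm.events[:, 2].astype(np.int64)
    )
    counts = np.bincount(flat, minlength=shape[0] * shape[1] * shape[2])
    return Sinogram(counts.reshape(shape).astype(np.float64), "prompts")


def bootstrap_listmode(lm: ListModeData, count_level: float, seed: int) -> ListModeData:
    """Resample events with replacement at a fractional count level."""
    if not (0 < count_level <= 1.0):
        raise ValueError("count_level must be in (0, 1]")
    if lm.n_events == 0:
        raise ValueError("cannot bootstrap an empty event list")
    n_out = int(round(count_level * lm.n_events))
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, lm.n_events, size=n_out)
    return ListModeData(lm.events[pick], source_frame=lm.source_frame, count_level=count_level)


# ----------------------------------------------------------------------
# persistence (HDF5)
# ----------------------------------------------------------------------
def save_listmode(lm: ListModeData, path: str | Path, seed: int | None = None) -> None:
    with h5py.File(str(path), "w") as f:
        ds = f.create_dataset("events", data=lm.events, dtype="int32")
        ds.attrs["frame_id"] = lm.source_frame
        ds.attrs["count_level"] = lm.count_level
        if seed is not None:
            ds.attrs["seed"] = int(seed)


def load_listmode(path: str | Path) -> ListModeData:
    with h5py.File(str(path), "r") as f:
        ds = f["events"]
        return ListModeData(
            ds[...],
            source_frame=str(ds.attrs.get("frame_id", "")),
            count_level=float(ds.attrs.get("count_level", 1.0)),
        )
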