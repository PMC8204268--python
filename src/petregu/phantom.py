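"""Seeded digital brain phantoms for registration-uncertainty experiments.

The phantom stands in for a real amyloid PET/MR acquisition: a parcellation
label volume, four per-frame activity patterns (early/late frames of an
amyloid-negative and an amyloid-positive scan), a 511-keV attenuation map and
a higher-resolution T1w-like structural image, all generated from parametric
nested ellipsoids so no external data is needed.

Anatomical layout (all geometry scales with the grid's physical extent):

* an outer skull shell (bone) around the brain,
* a cortical grey-matter ribbon over a white-matter core with a central
  CSF ventricle,
* a cerebellar compartment with a thin GM shell over a WM core,
* small single-blob cortical ROIs carved from the ribbon (cingulate gyri,
  precuneus, parietal and temporal patches) plus a hippocampus inside the
  white matter.

The precuneus analogue (``PRC``) is the SUVr target region and the
cerebellar grey matter (``CRB GM``) the reference region.  The precuneus is
a thick cortical patch bordered mostly by skull/CSF, while the cerebellar
shell is thin and backed by cerebellar WM — the geometry that drives
partial-volume spill in opposite directions for the two late-frame
contrasts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grid import VoxelGrid, default_affine

__all__ = [
    "Region",
    "RegionTable",
    "FrameSpec",
    "FRAME_SPECS",
    "PhantomError",
    "make_phantom",
    "make_activity",
    "MU_SOFT_TISSUE",
    "MU_BONE",
]

# 511 keV linear attenuation coefficients, per mm
MU_SOFT_TISSUE = 0.0096
MU_BONE = 0.0151

ROLES = ("target", "reference", "other")
TISSUES = ("GM", "WM", "CSF", "bone", "air")


class PhantomError(ValueError):
    """Raised when a phantom cannot be constructed on the requested grid."""


@dataclass(frozen=True)
class Region:
    label_id: int
    name: str
    role: str
    tissue: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")


@dataclass
class RegionTable:
    """Parcellation lookup: label id -> (name, role, tissue)."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.label_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate label ids in RegionTable")
        n_ref = sum(r.role == "reference" for r in self.regions)
        n_tgt = sum(r.role == "target" for r in self.regions)
        if n_ref != 1:
            raise ValueError(f"exactly one reference region required, got {n_ref}")
        if n_tgt < 1:
            raise ValueError("at least one target region required")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def by_name(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def id_of(self, name: str) -> int:
        return self.by_name(name).label_id

    @property
    def target(self) -> Region:
        return next(r for r in self.regions if r.role == "target")

    @property
    def reference(self) -> Region:
        return next(r for r in self.regions if r.role == "reference")

    def ids_for_tissue(self, tissue: str) -> list[int]:
        return [r.label_id for r in self.regions if r.tissue == tissue]

    def cortical_gm_ids(self) -> list[int]:
        """Cerebral-cortex GM labels (excludes cerebellum and hippocampus)."""
        skip = {"CRB GM", "HPC"}
        return [
            r.label_id
            for r in self.regions
            if r.tissue == "GM" and r.name not in skip
        ]

    def analysis_roi_names(self) -> list[str]:
        """The nine grey-matter-dominant ROIs used in the uncertainty matrices."""
        return ["ACG", "MCG", "PCG", "HPC", "PRC", "PRT", "TMP", "CRB GM", "CRB WM"]

    # -- CSV sidecar ----------------------------------------------------
    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        buf.write("label_id,name,role,tissue\n")
        for r in sorted(self.regions, key=lambda r: r.label_id):
            buf.write(f"{r.label_id},{r.name},{r.role},{r.tissue}\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionTable":
        lines = Path(path).read_text().strip().splitlines()
        regions = []
        for line in lines[1:]:
            lid, name, role, tissue = line.split(",")
            regions.append(Region(int(lid), name, role, tissue))
        return cls(regions)


@dataclass(frozen=True)
class FrameSpec:
    """Piecewise-constant tissue activities for one emulated PET frame.

    ``late_neg`` carries high GM:WM contrast while ``late_pos`` has the
    contrast between grey and white matter lost (GM close to WM); the early
    frames share a single flow-like pattern for both amyloid statuses.
    """

    frame_id: str
    gm_activity: float
    wm_activity: float
    csf_activity: float
    total_expected_counts: int

    def __post_init__(self) -> None:
        if self.frame_id not in ("early_neg", "late_neg", "early_pos", "late_pos"):
            raise ValueError(f"unknown frame_id {self.frame_id!r}")
        if self.total_expected_counts < 0:
            raise ValueError("total_expected_counts must be non-negative")


#: Default study frames.  CSF is fixed at 5% of WM activity in every frame.
FRAME_SPECS: dict[str, FrameSpec] = {
    "early_neg": FrameSpec("early_neg", 1.8, 1.0, 0.05, 1_000_000),
    "early_pos": FrameSpec("early_pos", 1.8, 1.0, 0.05, 1_000_000),
    "late_neg": FrameSpec("late_neg", 2.2, 1.0, 0.05, 2_000_000),
    "late_pos": FrameSpec("late_pos", 1.0, 1.0, 0.05, 2_000_000),
}


# ----------------------------------------------------------------------
# label ids
# ----------------------------------------------------------------------
AIR, SKULL, CSF, WM, CTX = 0, 1, 2, 3, 4
ACG, MCG, PCG, HPC, PRC, PRT, TMP, CRB_GM, CRB_WM = 5, 6, 7, 8, 9, 10, 11, 12, 13

_REGION_DEFS = [
    (SKULL, "SKULL", "other", "bone"),
    (CSF, "CSF", "other", "CSF"),
    (WM, "WM", "other", "WM"),
    (CTX, "CTX", "other", "GM"),
    (ACG, "ACG", "other", "GM"),
    (MCG, "MCG", "other", "GM"),
    (PCG, "PCG", "other", "GM"),
    (HPC, "HPC", "other", "GM"),
    (PRC, "PRC", "target", "GM"),
    (PRT, "PRT", "other", "GM"),
    (TMP, "TMP", "other", "GM"),
    (CRB_GM, "CRB GM", "reference", "GM"),
    (CRB_WM, "CRB WM", "other", "WM"),
]

# physical shell thicknesses (mm)
_SKULL_THICKNESS = 6.0
_RIBBON_THICKNESS = 8.5
_CRB_SHELL = 4.0

# ellipsoid semi-axes as fractions of the grid half-extent
_F_BRAIN = np.array([0.72, 0.88, 0.81])
# longitudinal fissure: midline CSF groove anchoring in-plane rotation
_FISSURE_HALF_WIDTH = 1.5
_FISSURE_FLOOR_Z = 2.0
_F_CRB_CENTER = np.array([0.0, -0.34, -0.46])
_F_CRB_SEMI = np.array([0.375, 0.28, 0.25])
_F_VENT_CENTER = np.array([0.0, 0.06, 0.125])
_F_VENT_SEMI = np.array([0.16, 0.22, 0.15])
_F_HPC_CENTER = np.array([0.34, -0.09, -0.29])
_HPC_SEMI_MM = np.array([5.0, 8.0, 5.0])

# cortical patches: name -> (theta_deg, phi_deg, radius_mm); the cingulate /
# precuneus analogues sit paramedian (one hemisphere) clear of the fissure
_PATCHES = {
    ACG: (75.0, 70.0, 7.0),
    MCG: (75.0, 28.0, 7.0),
    PCG: (290.0, 48.0, 7.0),
    PRC: (312.0, 26.0, 9.0),
    PRT: (180.0, 42.0, 11.0),
    TMP: (0.0, 100.0, 13.0),
}


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _paint_labels(shape, voxel_size_mm, affine) -> np.ndarray:
    """Rasterize the parametric anatomy onto a grid (any resolution)."""
    shape = tuple(int(n) for n in shape)
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    # world coordinates of voxel centres
    A = affine
    x = A[0, 0] * idx[0] + A[0, 1] * idx[1] + A[0, 2] * idx[2] + A[0, 3]
    y = A[1, 0] * idx[0] + A[1, 1] * idx[1] + A[1, 2] * idx[2] + A[1, 3]
    z = A[2, 0] * idx[0] + A[2, 1] * idx[1] + A[2, 2] * idx[2] + A[2, 3]
    coords = (x, y, z)

    half = np.asarray(shape) * np.asarray(voxel_size_mm) / 2.0
    brain_semi = _F_BRAIN * half
    head_semi = brain_semi + _SKULL_THICKNESS
    ctx_inner = brain_semi - _RIBBON_THICKNESS
    if np.any(ctx_inner <= 0):
        raise PhantomError("grid too small to contain region WM (cortical core)")

    labels = np.zeros(shape, dtype=np.int16)
    origin = np.zeros(3)

    head = _ellipsoid(coords, origin, head_semi)
    brain = _ellipsoid(coords, origin, brain_semi)
    core = _ellipsoid(coords, origin, ctx_inner)
    labels[head & ~brain] = SKULL
    labels[brain & ~core] = CTX
    labels[core] = WM

    vent = _ellipsoid(coords, _F_VENT_CENTER * half, _F_VENT_SEMI * half)
    labels[vent & core] = CSF

    hpc = _ellipsoid(coords, _F_HPC_CENTER * half, _HPC_SEMI_MM)
    labels[hpc & core] = HPC

    # longitudinal fissure: carves the superior midline down to the
    # ventricle, giving the transaxial plane a rotational anchor
    fissure = (np.abs(x) < _FISSURE_HALF_WIDTH) & (z > _FISSURE_FLOOR_Z) & brain
    labels[fissure & ((labels == CTX) | (labels == WM))] = CSF

    # cortical patches on the mid-ribbon surface
    mid = brain_semi - _RIBBON_THICKNESS / 2.0
    for lid, (theta, phi, radius) in _PATCHES.items():
        th, ph = np.deg2rad(theta), np.deg2rad(phi)
        c = np.array(
            [
                mid[0] * np.sin(ph) * np.cos(th),
                mid[1] * np.sin(ph) * np.sin(th),
                mid[2] * np.cos(ph),
            ]
        )
        sphere = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= radius**2
        labels[sphere & (labels == CTX)] = lid

    # cerebellum painted last: overrides cerebral tissue where they meet
    crb_c = _F_CRB_CENTER * half
    crb_semi = _F_CRB_SEMI * half
    crb_in = crb_semi - _CRB_SHELL
    if np.any(crb_in <= 0):
        raise PhantomError("grid too small to contain region CRB WM")
    crb = _ellipsoid(coords, crb_c, crb_semi) & brain
    crb_core = _ellipsoid(coords, crb_c, crb_in) & brain
    labels[crb] = CRB_GM
    labels[crb_core] = CRB_WM

    # carving (fissure, cerebellum) can strand voxel-scale slivers;
    # absorb any minor component into its dominant neighbouring label
    for lid in (CTX, WM, ACG, MCG, PCG, PRC, PRT, TMP, HPC):
        _absorb_minor_components(labels, lid)

    return labels


def _absorb_minor_components(labels: np.ndarray, lid: int) -> None:
    """Reassign all but the largest 6-connected component of label ``lid``."""
    from scipy import ndimage

    mask = labels == lid
    if not mask.any():
        return
    comp, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n <= 1:
        return
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    for c in range(1, n + 1):
        if c == keep:
            continue
        m = comp == c
        ring = ndimage.binary_dilation(m, ndimage.generate_binary_structure(3, 1)) & ~m
        neigh = labels[ring]
        neigh = neigh[neigh != lid]
        if neigh.size == 0:
            continue
        labels[m] = np.bincount(neigh).argmax()


_T1W_INTENSITY = {
    AIR: 0.0,
    SKULL: 0.15,
    CSF: 0.25,
    WM: 1.0,
    CRB_WM: 1.0,
}
_T1W_GM = 0.55
_T1W_NOISE_FRAC = 0.01  # of WM intensity


def make_phantom(
    seed: int,
    grid_shape: tuple[int, int, int] = (64, 64, 48),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> tuple[VoxelGrid, RegionTable, VoxelGrid, VoxelGrid]:
    """Build a seeded digital brain phantom.

    Returns
    -------
    labels:
        Integer parcellation on the PET grid.
    regions:
        The :class:`RegionTable` describing every label.
    mu_map:
        511-keV attenuation map (per mm) on the PET grid.
    t1w:
        T1w-like structural image on a grid with half the voxel size
        (double the resolution), with 1%-of-WM additive Gaussian noise.

    Identical seeds yield bit-identical phantoms.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if any(n < 16 for n in grid_shape):
        raise PhantomError("grid_shape must be at least 16 along every axis")
    voxel_size_mm = tuple(float(v) for v in voxel_size_mm)

    affine = default_affine(grid_shape, voxel_size_mm)
    lab = _paint_labels(grid_shape, voxel_size_mm, affine)
    regions = RegionTable([Region(*d) for d in _REGION_DEFS])

    for r in regions:
        if not np.any(lab == r.label_id):
            raise PhantomError(f"grid too small to contain region {r.name}")

    labels = VoxelGrid(lab, voxel_size_mm, affine)

    mu = np.zeros(grid_shape, dtype=np.float64)
    mu[lab == SKULL] = MU_BONE
    mu[(lab != AIR) & (lab != SKULL)] = MU_SOFT_TISSUE
    mu_map = VoxelGrid(mu, voxel_size_mm, affine)

    # T1w on double resolution, same physical extent and world frame
    t1_shape = tuple(2 * n for n in grid_shape)
    t1_vox = tuple(v / 2.0 for v in voxel_size_mm)
    t1_aff = default_affine(t1_shape, t1_vox)
    t1_lab = _paint_labels(t1_shape, t1_vox, t1_aff)
    t1 = np.full(t1_lab.shape, _T1W_GM, dtype=np.float64)
    for lid, inten in _T1W_INTENSITY.items():
        t1[t1_lab == lid] = inten
    rng = np.random.default_rng(seed)
    t1 = t1 + rng.normal(0.0, _T1W_NOISE_FRAC * 1.0, size=t1.shape)
    t1w = VoxelGrid(t1, t1_vox, t1_aff)

    return labels, regions, mu_map, t1w


def make_activity(
    labels: VoxelGrid,
    regions: RegionTable,
    frame: FrameSpec,
    sys=None,
) -> VoxelGrid:
    """Piecewise-constant activity for one frame, calibrated in counts.

    The tissue-class pattern from ``frame`` is scaled so that the noiseless
    forward projection through ``sys`` (the default system model for this
    grid when not given) yields ``frame.total_expected_counts`` in total.
    """
    lab = labels.values
    act = np.zeros(lab.shape, dtype=np.float64)
    tissue_activity = {
        "GM": frame.gm_activity,
        "WM": frame.wm_activity,
        "CSF": frame.csf_activity,
        "bone": 0.0,
        "air": 0.0,
    }
    for r in regions:
        act[lab == r.label_id] = tissue_activity[r.tissue]

    if frame.total_expected_counts == 0:
        return labels.copy(values=np.zeros_like(act))

    from .simulate import default_system, forward_project

    grid = labels.copy(values=act)
    if sys is None:
        sys = default_system(grid)
    total = float(forward_project(grid, sys).values.sum())
    if total <= 0:
        raise PhantomError("phantom activity projects to zero counts")
    return labels.copy(values=act * (frame.total_expected_counts / total))
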