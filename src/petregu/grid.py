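"""Image-domain container and voxel-grid geometry.

A :class:`VoxelGrid` is the universal carrier for every image-domain object in
the pipeline: PET activity and reconstructions, the attenuation (mu) map, a
T1w-like structural image, and integer parcellation labels.  World geometry
follows the NIfTI convention: ``world_mm = affine @ [i, j, k, 1]`` with
0-based voxel indices and RAS-oriented axes for unrotated grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "default_affine",
    "upsample_split",
    "block_downsample",
]


def default_affine(shape, voxel_size_mm) -> np.ndarray:
    """Diagonal affine centring the grid on the world origin."""
    shape = np.asarray(shape, dtype=float)
    vox = np.asarray(voxel_size_mm, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vox)
    # centre of voxel grid maps to world (0,0,0)
    aff[:3, 3] = -vox * (shape - 1) / 2.0
    return aff


@dataclass
class VoxelGrid:
    """A 3-D image with voxel size and a voxel-to-world affine.

    Parameters
    ----------
    values:
        Array of shape ``shape``; non-negative for activity/mu/counts,
        integer-valued for label volumes.
    voxel_size_mm:
        Physical voxel dimensions, one per axis.
    affine:
        4x4 matrix mapping homogeneous 0-based voxel indices to world mm.
        Defaults to a centred diagonal affine built from ``voxel_size_mm``.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"VoxelGrid requires 3-D values, got {self.values.ndim}-D")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.affine is None:
            self.affine = default_affine(self.values.shape, self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    def copy(self, values: np.ndarray | None = None) -> "VoxelGrid":
        """Shallow geometric copy, optionally with new values on the same grid."""
        v = self.values.copy() if values is None else np.asarray(values)
        return VoxelGrid(v, self.voxel_size_mm, self.affine.copy())

    # ------------------------------------------------------------------
    # geometry helpers
    # ------------------------------------------------------------------
    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices (may be fractional) to world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        hom = np.c_[xyz, np.ones(len(xyz))]
        return (np.linalg.inv(self.affine) @ hom.T).T[:, :3]

    def world_center(self) -> np.ndarray:
        """World coordinate of the grid centre (mm)."""
        c = (np.asarray(self.shape, dtype=float) - 1) / 2.0
        return self.voxel_to_world(c)[0]

    # ------------------------------------------------------------------
    # I/O  (NIfTI-1)
    # ------------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asanyarray(self.values), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelGrid":
        img = nib.load(str(path))
        aff = img.affine
        vox = np.linalg.norm(aff[:3, :3], axis=0)
        return cls(np.asanyarray(img.dataobj), tuple(vox), aff)


def upsample_split(img: VoxelGrid) -> VoxelGrid:
    """Split each voxel into eight equal voxels, without interpolation.

    Every output voxel carries the value of its parent, the voxel size is
    halved, and the affine is adjusted so that world positions (e.g. of
    region centroids) are preserved.
    """
    vals = img.values
    out = vals.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)
    # child index j corresponds to parent continuous index (j - 0.5) / 2
    split = np.eye(4)
    split[:3, :3] *= 0.5
    split[:3, 3] = -0.25
    new_aff = img.affine @ split
    new_vox = tuple(v / 2.0 for v in img.voxel_size_mm)
    return VoxelGrid(out, new_vox, new_aff)


def block_downsample(img: VoxelGrid) -> VoxelGrid:
    """2x2x2 block-mean downsampling; inverse of :func:`upsample_split` values."""
    s = img.values.shape
    if any(n % 2 for n in s):
        raise ValueError("block_downsample requires even dimensions")
    v = img.values.reshape(s[0] // 2, 2, s[1] // 2, 2, s[2] // 2, 2)
    out = v.mean(axis=(1, 3, 5))
    merge = np.eye(4)
    merge[:3, :3] *= 2.0
    merge[:3, 3] = 0.5
    new_aff = img.affine @ merge
    new_vox = tuple(v * 2.0 for v in img.voxel_size_mm)
    return VoxelGrid(out, new_vox, new_aff)
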