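"""Voxel-grid geometry shared by all images and masks in a study.

All quantitative stages of the pipeline refuse to mix images that do not
live on the same grid: resampling is deliberately out of scope (images are
assumed co-registered upstream), so grid compatibility is the contract that
guards every voxelwise operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Relative tolerance for declaring two grids compatible.
GRID_RTOL = 1e-5


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a 3-D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    voxel_size
        Voxel edge lengths in mm, all strictly positive.
    affine
        4x4 voxel-index -> world (mm) map. Must be invertible.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        voxel_size = tuple(float(v) for v in self.voxel_size)
        affine = np.asarray(self.affine, dtype=float)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if len(voxel_size) != 3 or any(v <= 0 for v in voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths (mm), got {voxel_size}")
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel_size)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int],
                  voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
                  origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "GridGeometry":
        """Axis-aligned grid with the given voxel size and world origin."""
        affine = np.diag(list(voxel_size) + [1.0])
        affine[:3, 3] = origin
        return cls(shape=tuple(shape), voxel_size=tuple(voxel_size), affine=affine)

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (from the affine, so shear-safe)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def is_compatible(self, other: "GridGeometry", rtol: float = GRID_RTOL) -> bool:
        """Same shape and same affine within relative tolerance."""
        if self.shape != other.shape:
            return False
        scale = max(np.max(np.abs(self.affine)), np.max(np.abs(other.affine)), 1.0)
        return bool(np.all(np.abs(self.affine - other.affine) <= rtol * scale))

    def require_compatible(self, other: "GridGeometry", what: str = "images") -> None:
        if not self.is_compatible(other):
            raise GridMismatchError(
                f"Incompatible grids for {what}: "
                f"shape {self.shape} / affine\n{self.affine}\n"
                f"vs shape {other.shape} / affine\n{other.affine}\n"
                "No resampling is performed; co-register inputs upstream."
            )

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World (mm) coordinates of every voxel center, one 3-D array per axis."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        m = self.affine
        x = m[0, 0] * ii + m[0, 1] * jj + m[0, 2] * kk + m[0, 3]
        y = m[1, 0] * ii + m[1, 1] * jj + m[1, 2] * kk + m[1, 3]
        z = m[2, 0] * ii + m[2, 1] * jj + m[2, 2] * kk + m[2, 3]
        return x, y, z


class GridMismatchError(ValueError):
    """Raised when two volumes do not share a compatible voxel grid."""
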