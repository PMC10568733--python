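"""Voxel grids, activity volumes and region masks.

World coordinates are right-handed and measured in millimetres. The origin
sits at the centre of the scanner field of view (FOV); ``x`` and ``y`` span
the transaxial plane and ``z`` runs along the bore (axial axis). A
:class:`VoxelGrid` ties an index lattice to world space through its voxel
size and the world position of the centre of voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "ActivityVolume", "RegionMask", "MASK_ROLES"]

#: Recognised region-mask roles.
MASK_ROLES = frozenset(
    {"striatum", "striatum_box", "background_voi", "whole_brain", "gray", "white"}
)


@dataclass(frozen=True)
class VoxelGrid:
    """A regular voxel lattice embedded in world (scanner) coordinates.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); each entry >= 1.
    voxel_size_mm
        Voxel edge lengths in mm along (x, y, z); each entry > 0.
    origin_mm
        World coordinate of the *centre* of voxel index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int] | int,
        voxel_size_mm: tuple[float, float, float] | float,
    ) -> "VoxelGrid":
        """Grid whose world extent is centred on the FOV origin."""
        if np.isscalar(shape):
            shape = (int(shape),) * 3
        if np.isscalar(voxel_size_mm):
            voxel_size_mm = (float(voxel_size_mm),) * 3
        shape = tuple(int(n) for n in shape)
        vs = tuple(float(s) for s in voxel_size_mm)
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, vs))
        return cls(shape, vs, origin)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """World extent (shape x voxel size) along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm[axis] * np.arange(n)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (X, Y, Z) world coordinates of all voxel centres."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points, shape (..., 3)."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)


@dataclass
class ActivityVolume:
    """A voxelised activity distribution (ground truth or reconstruction)."""

    grid: VoxelGrid
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity values must be finite")
        if np.any(self.values < 0):
            raise ValueError("activity values must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def copy_with(self, values: np.ndarray, label: str | None = None) -> "ActivityVolume":
        return ActivityVolume(self.grid, values, self.label if label is None else label)


@dataclass
class RegionMask:
    """Boolean voxel mask on a grid, tagged with its analysis role."""

    grid: VoxelGrid
    member: np.ndarray
    role: str = ""

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.member.shape} does not match grid {self.grid.shape}"
            )
        if not self.member.any():
            raise ValueError(f"region mask {self.role!r} is empty")
        if self.role and self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())
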