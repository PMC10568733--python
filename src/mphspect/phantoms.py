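"""Digital phantoms: surrogate brain, Derenzo hot-rod and star patterns.

The brain phantom is a parametric ellipsoid surrogate for a NURBS-based
human head: an ellipsoidal brain containing a cortical gray-matter shell, a
white-matter interior, zero-uptake ventricles and two mirrored striatal
nuclei. Two tracer modes are provided:

* ``HMPAO`` (cerebral perfusion): gray matter takes ``gray_white_ratio``
  times the white-matter uptake; the striata sit at the gray level.
* ``TRODAT`` (dopamine-transporter): uniform background tissue with hot
  striata such that the striatal binding ratio, SBR = mean(striatum) /
  mean(background VOI) - 1, equals ``target_sbr`` exactly on the ground
  truth.

All structures are rasterised by voxel-centre inclusion (no anti-aliasing),
so piecewise-constant uptake ratios hold to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import PlacementError
from .grids import ActivityVolume, RegionMask, VoxelGrid

__all__ = [
    "BrainPhantomSpec",
    "make_brain_phantom",
    "make_derenzo",
    "derenzo_rod_centers",
    "make_star",
    "DEFAULT_ROD_DIAMETERS_MM",
]

#: Hot-rod diameters (mm) of the default six-sector Derenzo pattern.
DEFAULT_ROD_DIAMETERS_MM = (4.8, 6.4, 7.9, 9.5, 11.1, 12.7)

# Ellipsoid geometry of the surrogate brain (semi-axes and centres, mm).
_BRAIN_SEMI = (75.0, 90.0, 65.0)
_WHITE_SEMI = (54.0, 65.0, 47.0)
_VENTRICLE_SEMI = (6.0, 16.0, 8.0)
_VENTRICLE_CENTERS = ((9.0, 8.0, 10.0), (-9.0, 8.0, 10.0))
_STRIATUM_SEMI = (11.0, 24.0, 10.0)
_STRIATUM_CENTERS = ((28.0, 12.0, 0.0), (-28.0, 12.0, 0.0))

# Analysis boxes in world mm: the uniform background VOI spans 10 x 7 x 9
# voxels and the striatum bounding box 29 x 23 x 17 voxels on the native
# 3.125 mm grid. Box centres are aligned so the native grid recovers those
# voxel counts exactly.
_VOXEL_MM = 3.125
_BACKGROUND_VOI_CENTER = (0.0, -39.0625, -1.5625)
_BACKGROUND_VOI_SIZE = (10 * _VOXEL_MM, 7 * _VOXEL_MM, 9 * _VOXEL_MM)
_STRIATUM_BOX_CENTER = (0.0, 12.0, 0.0)
_STRIATUM_BOX_SIZE = (29 * _VOXEL_MM, 23 * _VOXEL_MM, 17 * _VOXEL_MM)


def default_brain_grid() -> VoxelGrid:
    """The native phantom grid: 64^3 voxels of 3.125 mm."""
    return VoxelGrid.centered(64, _VOXEL_MM)


@dataclass
class BrainPhantomSpec:
    """Specification of the surrogate brain phantom."""

    tracer: str = "HMPAO"
    gray_white_ratio: float = 10.0
    target_sbr: float = 9.0
    grid: VoxelGrid | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        tracer = str(self.tracer).upper()
        if tracer not in {"HMPAO", "TRODAT"}:
            raise ValueError(f"tracer must be HMPAO or TRODAT, got {self.tracer!r}")
        self.tracer = tracer
        if self.gray_white_ratio <= 0:
            raise ValueError("gray_white_ratio must be positive")
        if self.target_sbr < 0:
            raise ValueError("target_sbr must be nonnegative")
        if self.grid is None:
            self.grid = default_brain_grid()


def _inside_ellipsoid(x, y, z, center, semi) -> np.ndarray:
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _inside_box(x, y, z, center, size) -> np.ndarray:
    # Half-open bounds so voxel counts are unambiguous when a bound falls on
    # a voxel-centre coordinate.
    out = np.ones(np.broadcast_shapes(x.shape, y.shape, z.shape), dtype=bool)
    for coord, c, s in ((x, center[0], size[0]), (y, center[1], size[1]), (z, center[2], size[2])):
        out &= (coord >= c - s / 2.0) & (coord < c + s / 2.0)
    return out


def make_brain_phantom(
    spec: BrainPhantomSpec | None = None,
) -> tuple[ActivityVolume, dict[str, RegionMask]]:
    """Generate the surrogate brain phantom and its analysis masks.

    Returns the activity volume together with masks keyed by role:
    ``whole_brain``, ``gray``, ``white``, ``striatum`` (the striatal
    ellipsoids themselves), ``striatum_box`` (the rectangular VOI used for
    striatal error metrics) and ``background_voi`` (the uniform box used for
    noise and SBR background measurements).
    """
    if spec is None:
        spec = BrainPhantomSpec()
    grid = spec.grid
    x, y, z = grid.voxel_centers()

    brain = _inside_ellipsoid(x, y, z, (0.0, 0.0, 0.0), _BRAIN_SEMI)
    white = _inside_ellipsoid(x, y, z, (0.0, 0.0, 0.0), _WHITE_SEMI)
    ventricles = np.zeros(grid.shape, dtype=bool)
    for c in _VENTRICLE_CENTERS:
        ventricles |= _inside_ellipsoid(x, y, z, c, _VENTRICLE_SEMI)
    striatum = np.zeros(grid.shape, dtype=bool)
    for c in _STRIATUM_CENTERS:
        striatum |= _inside_ellipsoid(x, y, z, c, _STRIATUM_SEMI)

    ventricles &= brain
    white &= brain
    striatum &= brain
    white_only = white & ~ventricles & ~striatum
    gray = brain & ~white & ~ventricles & ~striatum

    values = np.zeros(grid.shape, dtype=float)
    if spec.tracer == "HMPAO":
        values[white_only] = 1.0
        values[gray] = spec.gray_white_ratio
        values[striatum] = spec.gray_white_ratio  # striata are gray-matter nuclei
    else:  # TRODAT: uniform tissue background, hot striata
        values[white_only | gray] = 1.0
        values[striatum] = spec.target_sbr + 1.0
    values[ventricles] = 0.0

    voi = _inside_box(x, y, z, _BACKGROUND_VOI_CENTER, _BACKGROUND_VOI_SIZE)
    if not voi.any():
        raise PlacementError("background VOI contains no voxels on this grid")
    voi_vals = values[voi]
    if not np.all(voi_vals == voi_vals.flat[0]):
        raise PlacementError("background VOI is not fully inside a uniform tissue region")

    striatum_box = _inside_box(x, y, z, _STRIATUM_BOX_CENTER, _STRIATUM_BOX_SIZE)

    masks = {
        "whole_brain": RegionMask(grid, brain, "whole_brain"),
        "gray": RegionMask(grid, gray, "gray"),
        "white": RegionMask(grid, white_only, "white"),
        "striatum": RegionMask(grid, striatum, "striatum"),
        "striatum_box": RegionMask(grid, striatum_box, "striatum_box"),
        "background_voi": RegionMask(grid, voi, "background_voi"),
    }
    volume = ActivityVolume(grid, values, label=f"brain-{spec.tracer.lower()}")
    return volume, masks


# ---------------------------------------------------------------------------
# Derenzo hot-rod phantom
# ---------------------------------------------------------------------------

def derenzo_rod_centers(
    rod_diameters_mm=DEFAULT_ROD_DIAMETERS_MM,
    container_radius_mm: float = 100.0,
) -> list[np.ndarray]:
    """Rod-centre coordinates per sector of the Derenzo pattern.

    Each diameter occupies one equal angular sector. Within a sector, rods
    sit on a triangular lattice with centre-to-centre spacing twice the rod
    diameter, oriented along the sector bisector. A rod is kept only if its
    circle lies wholly inside the container and wholly inside its sector
    (with half-a-diameter clearance from the sector boundary rays).

    Returns a list of (n_rods, 2) arrays of (x, y) centres, one per sector.
    """
    diameters = [float(d) for d in rod_diameters_mm]
    if not diameters or any(d <= 0 for d in diameters):
        raise ValueError("rod diameters must be positive")
    if container_radius_mm <= 0:
        raise ValueError("container radius must be positive")
    n_sec = len(diameters)
    sector_angle = 2.0 * np.pi / n_sec

    centers: list[np.ndarray] = []
    n_omitted = 0
    for s, d in enumerate(diameters):
        spacing = 2.0 * d
        bisector = (s + 0.5) * sector_angle
        # Triangular lattice anchored at the origin, rows perpendicular to
        # the bisector; then rotated so rows stack outward along it.
        n_max = int(np.ceil(container_radius_mm / spacing)) + 2
        pts = []
        for j in range(-n_max, n_max + 1):
            v = j * spacing * np.sqrt(3.0) / 2.0
            off = 0.5 * spacing if j % 2 else 0.0
            for k in range(-n_max, n_max + 1):
                u = k * spacing + off
                pts.append((u, v))
        pts = np.asarray(pts)
        cosb, sinb = np.cos(bisector), np.sin(bisector)
        # Lattice (u, v) -> world: v runs along the bisector, u across it.
        xy = np.column_stack(
            [pts[:, 0] * -sinb + pts[:, 1] * cosb, pts[:, 0] * cosb + pts[:, 1] * sinb]
        )
        r = np.hypot(xy[:, 0], xy[:, 1])
        inside_container = r + d / 2.0 <= container_radius_mm

        if n_sec > 1:
            ang = np.mod(np.arctan2(xy[:, 1], xy[:, 0]), 2.0 * np.pi)
            rel = np.mod(ang - s * sector_angle, 2.0 * np.pi)
            in_wedge = rel < sector_angle
            # clearance of the full circle from both boundary rays
            lo = np.minimum(rel, sector_angle - rel)
            clear = r * np.sin(np.minimum(lo, np.pi / 2.0)) >= d
            in_sector = in_wedge & clear
        else:
            in_sector = np.ones(len(xy), dtype=bool)

        keep = in_sector & inside_container
        # a rod is "omitted" when its centre fits but its rim pokes out
        n_omitted += int(np.count_nonzero(in_sector & (r <= container_radius_mm) & ~inside_container))
        centers.append(xy[keep])

    if n_omitted:
        warnings.warn(
            f"{n_omitted} rod(s) spilling outside the container were omitted",
            stacklevel=2,
        )
    return centers


def default_slice_grid(n: int = 64, voxel_mm: float = _VOXEL_MM) -> VoxelGrid:
    """Single-slice grid used by the 2D phantoms."""
    return VoxelGrid.centered((n, n, 1), (voxel_mm, voxel_mm, voxel_mm))


def make_derenzo(
    rod_diameters_mm=DEFAULT_ROD_DIAMETERS_MM,
    container_radius_mm: float = 100.0,
    grid: VoxelGrid | None = None,
) -> ActivityVolume:
    """Rasterise the Derenzo hot-rod phantom (rods 1, background 0)."""
    if grid is None:
        grid = default_slice_grid()
    centers = derenzo_rod_centers(rod_diameters_mm, container_radius_mm)
    x, y, _ = grid.voxel_centers()
    values = np.zeros(grid.shape, dtype=float)
    for d, sec in zip(rod_diameters_mm, centers):
        rad2 = (float(d) / 2.0) ** 2
        for cx, cy in sec:
            values[((x - cx) ** 2 + (y - cy) ** 2 <= rad2)] = 1.0
    return ActivityVolume(grid, values, label="derenzo")


def make_star(
    n_columns: int = 32,
    container_radius_mm: float = 100.0,
    grid: VoxelGrid | None = None,
) -> ActivityVolume:
    """Alternating hot/cold angular wedges (a resolution "star" pattern).

    ``n_columns`` equal wedges of 360/n_columns degrees alternate between
    activity 1 and 0 inside the container circle.
    """
    n_columns = int(n_columns)
    if n_columns < 2 or n_columns % 2:
        raise ValueError("n_columns must be an even integer >= 2")
    if grid is None:
        grid = default_slice_grid()
    x, y, _ = grid.voxel_centers()
    wedge = 2.0 * np.pi / n_columns
    theta = np.mod(np.arctan2(y, x), 2.0 * np.pi)
    hot = (np.floor(theta / wedge).astype(int) % 2) == 0
    inside = x**2 + y**2 <= container_radius_mm**2
    values = np.where(hot & inside, 1.0, 0.0) * np.ones(grid.shape)
    return ActivityVolume(grid, values, label="star")
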