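"""Multi-pinhole collimator design and dual-head acquisition orbits.

Two collimator families are supported, both mounted on a dual-head camera
with a 540 x 400 mm detector (3.2 mm intrinsic resolution):

* ``MPGP`` — general purpose, 12 mm target planar system resolution
  (cerebral perfusion imaging);
* ``MPHR`` — high resolution, 8 mm target (striatal imaging).

A design is parameterised by the number of pinholes. Pinholes are laid out
on a centred near-square grid on the collimator plate, each tilted toward
the centre of the 200 mm spherical field of view (focused geometry). The
focal length is the largest value for which every pinhole's FOV footprint
fits on the detector while the total projection overlap stays below 20%;
the aperture diameter is then solved from the planar system-resolution
formula so that the resolution at the radius of rotation equals the target.

Geometry convention: world coordinates are right-handed with the origin at
the FOV centre and ``z`` along the bore. A head at gantry angle 0 looks
down the ``+x`` axis; its collimator plate lies in the plane ``x = ROR``
and the detector in ``x = ROR + f``. Gantry angles are measured
counter-clockwise about ``z``. Design-local coordinates below are simply
world coordinates of the gantry-angle-0 head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DesignInfeasibleError, GeometryError, OrbitError

__all__ = [
    "DetectorSpec",
    "PinholeSpec",
    "CollimatorDesign",
    "DetectorPose",
    "Orbit",
    "design_collimator",
    "pinhole_system_resolution",
    "collimator_sensitivity",
    "projection_overlap_fraction",
    "make_orbit",
    "pinhole_grid_layout",
]

#: Target planar system resolution (mm) per collimator family.
FAMILY_TARGET_RESOLUTION_MM = {"MPGP": 12.0, "MPHR": 8.0}

DEFAULT_ROR_MM = 135.0
DEFAULT_FOV_DIAMETER_MM = 200.0
OVERLAP_LIMIT = 0.20


@dataclass(frozen=True)
class DetectorSpec:
    """Gamma-camera head: NaI plate dimensions and intrinsic blur."""

    width_mm: float = 540.0
    height_mm: float = 400.0
    intrinsic_resolution_mm: float = 3.2
    pixel_size_mm: float = 3.2
    crystal_thickness_mm: float = 9.525

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("detector dimensions must be positive")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be positive")

    def n_pixels(self, pixel_size_mm: float | None = None) -> tuple[int, int]:
        """(columns along width, rows along height) at the given binning."""
        px = self.pixel_size_mm if pixel_size_mm is None else float(pixel_size_mm)
        return int(round(self.width_mm / px)), int(round(self.height_mm / px))


@dataclass(frozen=True)
class PinholeSpec:
    """One knife-edge pinhole on the collimator plate.

    ``plate_position_mm`` is the (transaxial, axial) offset of the aperture
    centre on the plate; ``tilt`` is the unit direction (design-local world
    coordinates) from the aperture toward the FOV centre.
    """

    plate_position_mm: tuple[float, float]
    aperture_diameter_mm: float
    acceptance_half_angle_deg: float
    tilt: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.aperture_diameter_mm < 0:
            raise ValueError("aperture diameter must be nonnegative")
        if self.acceptance_half_angle_deg <= 0:
            raise ValueError("acceptance half-angle must be positive")


@dataclass(frozen=True)
class CollimatorDesign:
    """Complete multi-pinhole geometry for one head."""

    family: str
    target_resolution_mm: float
    n_pinholes: int
    pinholes: tuple[PinholeSpec, ...]
    focal_length_mm: float
    ror_mm: float = DEFAULT_ROR_MM
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    fov_diameter_mm: float = DEFAULT_FOV_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.family not in FAMILY_TARGET_RESOLUTION_MM:
            raise ValueError(f"family must be one of {sorted(FAMILY_TARGET_RESOLUTION_MM)}")
        if self.n_pinholes != len(self.pinholes):
            raise ValueError("n_pinholes must equal len(pinholes)")
        if not 1 <= self.n_pinholes <= 25:
            raise ValueError("n_pinholes must be in 1..25")
        if self.focal_length_mm <= 0:
            raise GeometryError("focal length must be positive")

    @property
    def fov_radius_mm(self) -> float:
        return self.fov_diameter_mm / 2.0

    @property
    def aperture_diameter_mm(self) -> float:
        """Common aperture diameter (identical for all pinholes)."""
        return self.pinholes[0].aperture_diameter_mm

    def aperture_positions(self) -> np.ndarray:
        """(n, 3) design-local world positions of the aperture centres."""
        out = np.empty((self.n_pinholes, 3))
        for i, ph in enumerate(self.pinholes):
            out[i] = (self.ror_mm, ph.plate_position_mm[0], ph.plate_position_mm[1])
        return out


@dataclass(frozen=True)
class DetectorPose:
    """One head position: gantry angle, which head, and its radius."""

    gantry_angle_deg: float
    head_index: int = 0
    radius_mm: float = DEFAULT_ROR_MM

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("pose radius must be positive")
        object.__setattr__(self, "gantry_angle_deg", float(self.gantry_angle_deg) % 360.0)


@dataclass(frozen=True)
class Orbit:
    """Ordered dual-head acquisition poses."""

    poses: tuple[DetectorPose, ...]
    mode: str
    start_angle_deg: float = 0.0
    rotation_increment_deg: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"H", "L"}:
            raise ValueError("mode must be 'H' or 'L'")
        angles = [p.gantry_angle_deg for p in self.poses]
        rounded = [round(a % 360.0, 9) for a in angles]
        if len(set(rounded)) != len(rounded):
            raise OrbitError(f"duplicate gantry angles in orbit: {sorted(rounded)}")

    @property
    def n_projections(self) -> int:
        return len(self.poses)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([p.gantry_angle_deg for p in self.poses])


# ---------------------------------------------------------------------------
# Resolution / sensitivity formulas
# ---------------------------------------------------------------------------

def pinhole_system_resolution(design: CollimatorDesign, source_distance_mm: float) -> float:
    """Planar system resolution (FWHM, mm) at a source-to-aperture distance.

    Combines the aperture projection and the intrinsic detector blur referred
    to object space:

        R_sys(b) = sqrt( (d_e (b + f) / f)^2 + (R_i b / f)^2 )

    with b the source distance, f the focal length, d_e the aperture
    diameter and R_i the intrinsic resolution.
    """
    b = float(source_distance_mm)
    if b <= 0:
        raise ValueError("source distance must be positive")
    f = design.focal_length_mm
    if f <= 0:
        raise GeometryError("focal length must be positive")
    d_e = design.aperture_diameter_mm
    r_i = design.detector.intrinsic_resolution_mm
    return float(np.hypot(d_e * (b + f) / f, r_i * b / f))


def collimator_sensitivity(
    design: CollimatorDesign, source_point=(0.0, 0.0, 0.0)
) -> float:
    """Geometric efficiency (accepted / emitted fraction) at a source point.

    Sum over pinholes of ``d_e^2 sin^3(theta) / (16 h^2)`` where ``h`` is
    the source-to-aperture distance and ``theta`` the ray's incidence angle
    onto the (tilted) pinhole plane.
    """
    p = np.asarray(source_point, dtype=float)
    if np.linalg.norm(p) > design.fov_radius_mm + 1e-9:
        raise GeometryError("source point outside the FOV sphere")
    total = 0.0
    for ph, a in zip(design.pinholes, design.aperture_positions()):
        d = a - p
        h = np.linalg.norm(d)
        sin_theta = abs(float(np.dot(d / h, np.asarray(ph.tilt))))
        total += ph.aperture_diameter_mm**2 * sin_theta**3 / (16.0 * h**2)
    return float(total)


# ---------------------------------------------------------------------------
# Footprint rasterisation (shared by the design search and the overlap metric)
# ---------------------------------------------------------------------------

def _footprint_cover(
    apertures: np.ndarray,
    cos_acceptance: np.ndarray,
    tilts: np.ndarray,
    s_coords: np.ndarray,
    t_coords: np.ndarray,
    detector_x_mm: float,
    fov_radius_mm: float,
) -> np.ndarray:
    """Boolean cover masks (n_pinholes, ns, nt) of the FOV sphere footprints.

    A detector point is covered by a pinhole if the straight line from the
    point through that aperture intersects the FOV sphere and lies inside
    the pinhole's acceptance cone.
    """
    S, T = np.meshgrid(s_coords, t_coords, indexing="ij")
    P = np.stack([np.full_like(S, detector_x_mm), S, T], axis=-1)  # (ns, nt, 3)
    covers = np.empty((len(apertures), *S.shape), dtype=bool)
    for k, (a, cacc, tilt) in enumerate(zip(apertures, cos_acceptance, tilts)):
        d = a[None, None, :] - P
        dn = np.linalg.norm(d, axis=-1)
        u = d / dn[..., None]
        # distance from the origin (FOV centre) to the infinite ray line
        proj = np.einsum("ijk,ijk->ij", P, u)
        closest = P - proj[..., None] * u
        dist = np.linalg.norm(closest, axis=-1)
        cone = np.einsum("ijk,k->ij", u, tilt) >= cacc
        covers[k] = (dist <= fov_radius_mm) & cone
    return covers


def pinhole_grid_layout(n_pinholes: int) -> list[int]:
    """Row structure of the centred near-square pinhole grid.

    Returns per-row pinhole counts, most populated rows toward the middle;
    ties in the grid shape are broken toward wider-than-tall to match the
    landscape detector.
    """
    n = int(n_pinholes)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    base, rem = divmod(n, rows)
    counts = sorted([base + 1] * rem + [base] * (rows - rem))
    # interleave so fuller rows sit in the middle: e.g. 7 -> [2, 3, 2]
    ordered = [0] * rows
    mid = rows // 2
    order = sorted(range(rows), key=lambda r: abs(r - (rows - 1) / 2.0))
    for slot, count in zip(order, reversed(counts)):
        ordered[slot] = count
    return [c for c in ordered if c > 0]


def _detector_cells(n_pinholes: int, detector: DetectorSpec):
    """Footprint-centre positions and their detector cells.

    The detector is tiled row by row: rows share the full width equally
    among that row's pinholes so sparse rows get wider cells ("projections
    fully utilising the coverage of the detector area").

    Returns (centers (n, 2), rects (n, 4) as (s_lo, s_hi, t_lo, t_hi)).
    """
    row_counts = pinhole_grid_layout(n_pinholes)
    rows = len(row_counts)
    cell_h = detector.height_mm / rows
    centers, rects = [], []
    for r, count in enumerate(row_counts):
        t = (r - (rows - 1) / 2.0) * cell_h
        cell_w = detector.width_mm / count
        for c in range(count):
            s = (c - (count - 1) / 2.0) * cell_w
            centers.append((s, t))
            rects.append((s - cell_w / 2.0, s + cell_w / 2.0, t - cell_h / 2.0, t + cell_h / 2.0))
    return np.asarray(centers), np.asarray(rects)


_CONE_PHI = np.linspace(0.0, 2.0 * np.pi, 73)


def _cone_half_angle_for_cell(
    aperture: np.ndarray, tilt: np.ndarray, rect, detector_x_mm: float, cap_rad: float
) -> float:
    """Largest acceptance half-angle whose cone footprint stays in the cell.

    The cone has its apex at the aperture and its axis along the tilt
    (toward the FOV centre); its intersection with the detector plane must
    fit the rectangle allotted to this pinhole.
    """
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(tilt, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(tilt, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tilt, e1)
    s_lo, s_hi, t_lo, t_hi = rect

    def fits(alpha: float) -> bool:
        d = (
            np.cos(alpha) * tilt[None, :]
            + np.sin(alpha)
            * (np.cos(_CONE_PHI)[:, None] * e1[None, :] + np.sin(_CONE_PHI)[:, None] * e2[None, :])
        )
        if np.any(d[:, 0] > -1e-9):  # a boundary ray runs parallel/away from the detector
            return False
        tau = (aperture[0] - detector_x_mm) / d[:, 0]
        p = aperture[None, :] - tau[:, None] * d
        return bool(
            np.all((p[:, 1] >= s_lo) & (p[:, 1] <= s_hi) & (p[:, 2] >= t_lo) & (p[:, 2] <= t_hi))
        )

    lo, hi = 0.0, cap_rad
    if fits(hi):
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if fits(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _fov_sample_points(fov_radius_mm: float, n_dirs: int = 192) -> np.ndarray:
    """Quasi-uniform sample points filling the FOV sphere (for coverage)."""
    i = np.arange(n_dirs)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_dirs
    r = np.sqrt(1.0 - z**2)
    phi = golden * i
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts = [np.zeros((1, 3))]
    for frac in (1.0, 0.85, 0.6, 0.3):
        pts.append(dirs * (frac * fov_radius_mm))
    return np.vstack(pts)


def _union_covers(
    apertures: np.ndarray, tilts: np.ndarray, alphas_rad: np.ndarray, points: np.ndarray
) -> bool:
    """Do the pinhole acceptance cones jointly cover all sample points?"""
    covered = np.zeros(len(points), dtype=bool)
    for a, tilt, alpha in zip(apertures, tilts, alphas_rad):
        v = points - a[None, :]
        vn = np.linalg.norm(v, axis=1)
        covered |= (v @ tilt) / vn >= np.cos(alpha)
        if covered.all():
            return True
    return bool(covered.all())


def design_collimator(
    family: str,
    n_pinholes: int,
    detector: DetectorSpec | None = None,
    ror_mm: float = DEFAULT_ROR_MM,
    fov_diameter_mm: float = DEFAULT_FOV_DIAMETER_MM,
    overlap_limit: float = OVERLAP_LIMIT,
    raster_pitch_mm: float = 2.0,
) -> CollimatorDesign:
    """Design an MPGP or MPHR collimator for a given pinhole count.

    The pinhole plate layout tiles the detector with one cell per pinhole.
    Each pinhole's acceptance cone is opened as wide as its cell permits
    (capped at the angle subtending the whole FOV sphere), which keeps every
    footprint on the detector and the projection overlap below
    ``overlap_limit`` by construction. The focal length is then maximised
    subject to (i) the acceptance cones jointly covering the entire FOV
    sphere — individual pinholes may view only a sub-volume, but nothing in
    the FOV may be invisible to the system — and (ii) the
    intrinsic-resolution term leaving room for a positive aperture at the
    target resolution. The aperture diameter follows from the
    system-resolution formula at the radius of rotation.

    Raises
    ------
    DesignInfeasibleError
        If no focal length satisfies all constraints (this can occur for
        the high-resolution family at large pinhole counts, where the short
        focal length required for joint FOV coverage conflicts with the
        8 mm resolution target).
    """
    family = str(family).upper()
    if family not in FAMILY_TARGET_RESOLUTION_MM:
        raise ValueError(f"unknown collimator family {family!r}")
    r_t = FAMILY_TARGET_RESOLUTION_MM[family]
    if detector is None:
        detector = DetectorSpec()
    if not 1 <= int(n_pinholes) <= 25:
        raise ValueError("n_pinholes must be in 1..25")
    n_pinholes = int(n_pinholes)
    fov_radius = fov_diameter_mm / 2.0
    r_i = detector.intrinsic_resolution_mm

    centers, rects = _detector_cells(n_pinholes, detector)

    # Resolution feasibility floor: R_i * ror / f must stay below R_t with
    # margin for a positive aperture diameter.
    f_min = r_i * ror_mm / (0.98 * r_t)
    samples = _fov_sample_points(fov_radius)

    def geometry(f: float):
        plate = centers / (1.0 + f / ror_mm)
        apertures = np.column_stack([np.full(n_pinholes, ror_mm), plate[:, 0], plate[:, 1]])
        norms = np.linalg.norm(apertures, axis=1)
        tilts = -apertures / norms[:, None]
        cap = np.arcsin(np.clip(fov_radius / norms, 0.0, 1.0)) + np.radians(0.5)
        alphas = np.array(
            [
                _cone_half_angle_for_cell(a, t, rect, ror_mm + f, c)
                for a, t, rect, c in zip(apertures, tilts, rects, cap)
            ]
        )
        return plate, apertures, tilts, alphas

    def feasible(f: float) -> bool:
        _, apertures, tilts, alphas = geometry(f)
        if np.any(alphas <= np.radians(1.0)):
            return False
        return _union_covers(apertures, tilts, alphas, samples)

    if not feasible(f_min):
        raise DesignInfeasibleError(
            f"{family} with {n_pinholes} pinholes: no focal length lets the acceptance "
            f"cones jointly cover the {fov_diameter_mm:g} mm FOV at the {r_t} mm target "
            "resolution"
        )
    f_lo, f_hi = f_min, 400.0
    if feasible(f_hi):
        f_best = f_hi
    else:
        while f_hi - f_lo > 0.25:
            mid = 0.5 * (f_lo + f_hi)
            if feasible(mid):
                f_lo = mid
            else:
                f_hi = mid
        f_best = f_lo

    f = float(f_best)
    ri_term = r_i * ror_mm / f
    d_e = float(np.sqrt(r_t**2 - ri_term**2) * f / (ror_mm + f))

    plate, _, tilts, alphas = geometry(f)
    pinholes = tuple(
        PinholeSpec(
            plate_position_mm=(float(pu), float(pv)),
            aperture_diameter_mm=d_e,
            acceptance_half_angle_deg=float(np.degrees(alpha)),
            tilt=tuple(float(c) for c in tilt),
        )
        for (pu, pv), tilt, alpha in zip(plate, tilts, alphas)
    )
    return CollimatorDesign(
        family=family,
        target_resolution_mm=r_t,
        n_pinholes=n_pinholes,
        pinholes=pinholes,
        focal_length_mm=f,
        ror_mm=ror_mm,
        detector=detector,
        fov_diameter_mm=fov_diameter_mm,
    )


def projection_overlap_fraction(
    design: CollimatorDesign, raster_pitch_mm: float = 1.0
) -> float:
    """Multiply-covered fraction of the covered detector area.

    Rasterises every pinhole's FOV-sphere footprint on the detector plane
    and returns area(covered by >= 2) / area(covered by >= 1).
    """
    apertures = design.aperture_positions()
    tilts = np.asarray([ph.tilt for ph in design.pinholes])
    cos_acc = np.cos(np.radians([ph.acceptance_half_angle_deg for ph in design.pinholes]))
    half_w = design.detector.width_mm / 2.0
    half_h = design.detector.height_mm / 2.0
    s = np.arange(-half_w + raster_pitch_mm / 2.0, half_w, raster_pitch_mm)
    t = np.arange(-half_h + raster_pitch_mm / 2.0, half_h, raster_pitch_mm)
    covers = _footprint_cover(
        apertures, cos_acc, tilts, s, t,
        design.ror_mm + design.focal_length_mm, design.fov_radius_mm,
    )
    count = covers.sum(axis=0)
    covered = int((count >= 1).sum())
    if covered == 0:
        return 0.0
    return float((count >= 2).sum()) / covered


# ---------------------------------------------------------------------------
# Orbits
# ---------------------------------------------------------------------------

def make_orbit(
    n_projections: int,
    mode: str = "H",
    start_angle_deg: float = 0.0,
    rotation_increment_deg: float | None = None,
    radius_mm: float = DEFAULT_ROR_MM,
) -> Orbit:
    """Dual-head orbit over 360 degrees.

    The two heads sit 180 degrees apart in H-mode and 90 degrees apart in
    L-mode. With ``rotation_increment_deg=None`` the head-0 positions are
    spaced so that the combined set of projections samples 360 degrees as
    uniformly as the mode permits (increment 360/n for H-mode, 720/n for
    L-mode). An explicit increment supports detector-position sweep
    protocols. Duplicate gantry angles raise :class:`OrbitError`.
    """
    n = int(n_projections)
    if n < 2 or n % 2:
        raise OrbitError("n_projections must be an even integer >= 2 (dual head)")
    mode = str(mode).upper()
    if mode not in {"H", "L"}:
        raise ValueError("mode must be 'H' or 'L'")
    if rotation_increment_deg is None:
        inc = 360.0 / n if mode == "H" else 720.0 / n
    else:
        inc = float(rotation_increment_deg)
    partner = 180.0 if mode == "H" else 90.0
    poses = []
    for k in range(n // 2):
        a0 = start_angle_deg + k * inc
        poses.append(DetectorPose(a0, head_index=0, radius_mm=radius_mm))
        poses.append(DetectorPose(a0 + partner, head_index=1, radius_mm=radius_mm))
    return Orbit(
        poses=tuple(poses),
        mode=mode,
        start_angle_deg=float(start_angle_deg),
        rotation_increment_deg=rotation_increment_deg,
    )
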