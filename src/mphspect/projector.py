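"""Analytical multi-pinhole forward model.

Projection is detector-pixel-driven: for each pose and pinhole, a ray is
cast from every candidate detector pixel centre through the aperture centre
and the activity is integrated along the ray inside the FOV sphere
(trilinear interpolation, steps of half the voxel size). Each sample is
weighted by the geometric pinhole efficiency ``d_e^2 sin^3(theta) /
(16 h^2)`` at its source position, so projections carry absolute
(efficiency-scaled) intensities. The finite system resolution is modelled
by a detector-space Gaussian whose FWHM equals the planar system resolution
at the radius of rotation mapped through the pinhole magnification; on a
point source at the FOV centre this reproduces the resolution formula
exactly.

Attenuation, scatter and aperture penetration are not modelled (perfect
corrections are assumed), matching the analytical-study design.

The same operator exposes its exact adjoint, which the ML-EM reconstruction
uses; matched forward/back pairs are essential for EM convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter

from .collimator import CollimatorDesign, DetectorPose, Orbit, pinhole_system_resolution
from .errors import GeometryError, ScalingError
from .grids import ActivityVolume, VoxelGrid

__all__ = [
    "SystemOperator",
    "ProjectionSet",
    "CountScalingParams",
    "forward_project",
    "simulate_acquisition",
    "scale_counts",
    "add_poisson_noise",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class CountScalingParams:
    """Clinical count-level scaling of noise-free projections.

    The scaled total count is

        C_s = C_ref * (n_p * S_MPH) / (n_ref * S_LEHR)

    where ``C_ref`` is the total count of the reference clinical scan
    acquired with ``n_ref`` views of a parallel-hole LEHR collimator of
    sensitivity ``S_LEHR``, and ``n_p``/``S_MPH`` describe the simulated
    multi-pinhole acquisition. ``n_p`` and ``S_MPH`` may be left ``None``
    to be resolved from the orbit and design at scaling time.
    """

    c_ref: float
    n_p: int | None = None
    s_mph: float | None = None
    n_ref: int = 120
    s_lehr: float = 1e-4  # LEHR sensitivity, 0.01%

    def __post_init__(self) -> None:
        if self.c_ref <= 0 or self.n_ref <= 0 or self.s_lehr <= 0:
            raise ValueError("scaling parameters must be positive")

    def scaled_total(self, n_p: int | None = None, s_mph: float | None = None) -> float:
        n_p = self.n_p if n_p is None else n_p
        s_mph = self.s_mph if s_mph is None else s_mph
        if n_p is None or s_mph is None:
            raise ValueError("n_p and s_mph must be provided or resolvable")
        if n_p <= 0 or s_mph <= 0:
            raise ValueError("n_p and s_mph must be positive")
        return float(self.c_ref) * (n_p * s_mph) / (self.n_ref * self.s_lehr)


@dataclass
class ProjectionSet:
    """Per-pose detector images plus acquisition metadata."""

    images: np.ndarray  # (n_projections, nu, nv)
    orbit: Orbit
    design: CollimatorDesign
    detector_pixel_mm: float
    total_counts: float = 0.0
    noise_seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] != self.orbit.n_projections:
            raise ValueError("images must be (n_projections, nu, nv)")
        if np.any(self.images < 0):
            raise ValueError("projection images must be nonnegative")
        self.total_counts = float(self.images.sum())

    @property
    def is_noisy(self) -> bool:
        return self.noise_seed is not None

    def copy_with(self, images: np.ndarray, **meta) -> "ProjectionSet":
        new_meta = dict(self.meta)
        noise_seed = meta.pop("noise_seed", self.noise_seed)
        new_meta.update(meta)
        return ProjectionSet(
            images=images,
            orbit=self.orbit,
            design=self.design,
            detector_pixel_mm=self.detector_pixel_mm,
            noise_seed=noise_seed,
            meta=new_meta,
        )


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class SystemOperator:
    """Forward/adjoint projection operator for one design, orbit and grid.

    The geometric part is a sparse matrix ``G`` mapping voxel activities to
    per-pose detector images; the resolution model is a symmetric Gaussian
    convolution ``B`` applied per image. The full operator is ``A = B G``
    with exact adjoint ``A^T = G^T B``.

    With ``materialize=False`` only the forward direction is available
    (computed on the fly, no matrix storage) — enough for simulating data.
    """

    def __init__(
        self,
        design: CollimatorDesign,
        orbit: Orbit | list[DetectorPose],
        grid: VoxelGrid,
        detector_pixel_mm: float | None = None,
        step_fraction: float = 0.5,
        materialize: bool = True,
    ) -> None:
        self.design = design
        self.poses = tuple(orbit.poses if isinstance(orbit, Orbit) else orbit)
        if not self.poses:
            raise GeometryError("orbit has no poses")
        self.grid = grid
        px = design.detector.pixel_size_mm if detector_pixel_mm is None else float(detector_pixel_mm)
        self.detector_pixel_mm = px
        self.nu, self.nv = design.detector.n_pixels(px)
        self.n_pixels = self.nu * self.nv
        self.n_poses = len(self.poses)
        self.step_mm = step_fraction * min(grid.voxel_size_mm)

        fwhm_det = (
            pinhole_system_resolution(design, design.ror_mm)
            * design.focal_length_mm
            / design.ror_mm
        )
        self.blur_sigma_px = fwhm_det * _FWHM_TO_SIGMA / px

        self._ray_geometry = self._build_ray_geometry()
        self.G: sp.csr_matrix | None = None
        if materialize:
            self.G = self._build_matrix()

    # -- geometry ----------------------------------------------------------

    def _pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        s = (np.arange(self.nu) - (self.nu - 1) / 2.0) * self.detector_pixel_mm
        t = (np.arange(self.nv) - (self.nv - 1) / 2.0) * self.detector_pixel_mm
        return s, t

    def _build_ray_geometry(self) -> list[dict]:
        """Pose-independent per-pinhole ray bundles in design-local frame."""
        d = self.design
        s, t = self._pixel_centers()
        S, T = np.meshgrid(s, t, indexing="ij")
        x_det = d.ror_mm + d.focal_length_mm
        P = np.stack([np.full_like(S, x_det), S, T], axis=-1).reshape(-1, 3)
        pix_idx_all = np.arange(self.n_pixels)
        fov_r = d.fov_radius_mm

        # axis-aligned bounding box of the voxel grid (outer voxel faces)
        lo = np.asarray(self.grid.origin_mm) - np.asarray(self.grid.voxel_size_mm) / 2.0
        hi = lo + np.asarray(self.grid.extent_mm)

        bundles = []
        for ph, a in zip(d.pinholes, d.aperture_positions()):
            tilt = np.asarray(ph.tilt)
            cos_acc = np.cos(np.radians(ph.acceptance_half_angle_deg))
            dvec = a[None, :] - P
            dist_pa = np.linalg.norm(dvec, axis=1)
            u = dvec / dist_pa[:, None]
            # intersect ray P + tau*u with the FOV sphere |p| = fov_r
            pu = np.einsum("ij,ij->i", P, u)
            disc = pu**2 - (np.einsum("ij,ij->i", P, P) - fov_r**2)
            hits = disc > 0
            cone = np.einsum("ij,j->i", u, tilt) >= cos_acc
            keep = hits & cone
            if not keep.any():
                bundles.append(None)
                continue
            Pk, uk, puk = P[keep], u[keep], pu[keep]
            sq = np.sqrt(disc[keep])
            t_near, t_far = -puk - sq, -puk + sq
            # clip to the grid bounding box so thin grids stay cheap
            with np.errstate(divide="ignore", invalid="ignore"):
                for ax in range(3):
                    t1 = (lo[ax] - Pk[:, ax]) / uk[:, ax]
                    t2 = (hi[ax] - Pk[:, ax]) / uk[:, ax]
                    para = np.abs(uk[:, ax]) < 1e-12
                    tmin = np.where(para, -np.inf, np.minimum(t1, t2))
                    tmax = np.where(para, np.inf, np.maximum(t1, t2))
                    outside = para & ((Pk[:, ax] < lo[ax]) | (Pk[:, ax] > hi[ax]))
                    tmin = np.where(outside, np.inf, tmin)
                    tmax = np.where(outside, -np.inf, tmax)
                    t_near = np.maximum(t_near, tmin)
                    t_far = np.minimum(t_far, tmax)
            valid = t_far > t_near
            if not valid.any():
                bundles.append(None)
                continue
            Pk, uk = Pk[valid], uk[valid]
            t_near, t_far = t_near[valid], t_far[valid]
            pix = pix_idx_all[keep][valid]
            tau_a = dist_pa[keep][valid]
            sin_theta = np.einsum("ij,j->i", uk, tilt)
            n_steps = np.maximum(np.ceil((t_far - t_near) / self.step_mm), 1).astype(int)
            bundles.append(
                dict(
                    pix=pix.astype(np.int64),
                    P=Pk,
                    u=uk,
                    t_near=t_near,
                    t_far=t_far,
                    tau_a=tau_a,
                    sin_theta=sin_theta,
                    n_steps=n_steps,
                    d_e=ph.aperture_diameter_mm,
                )
            )
        return bundles

    def _samples(self, bundle: dict):
        """Sample positions (local frame), weights and ray pixel indices."""
        n_steps = bundle["n_steps"]
        max_n = int(n_steps.max())
        ds = (bundle["t_far"] - bundle["t_near"]) / n_steps
        steps = np.arange(max_n)
        tau = bundle["t_near"][:, None] + (steps[None, :] + 0.5) * ds[:, None]
        valid = steps[None, :] < n_steps[:, None]
        pos = bundle["P"][:, None, :] + bundle["u"][:, None, :] * tau[..., None]
        h = tau - bundle["tau_a"][:, None]
        w = (
            ds[:, None]
            * bundle["d_e"] ** 2
            * bundle["sin_theta"][:, None] ** 3
            / (16.0 * h**2)
        )
        rows = np.broadcast_to(bundle["pix"][:, None], tau.shape)
        return pos[valid], w[valid], rows[valid]

    def _trilinear(self, pos_world: np.ndarray):
        """Neighbour voxel flat indices and weights for world sample points."""
        g = self.grid
        idx = (pos_world - np.asarray(g.origin_mm)) / np.asarray(g.voxel_size_mm)
        i0 = np.floor(idx).astype(np.int64)
        frac = idx - i0
        nx, ny, nz = g.shape
        out_idx = []
        out_w = []
        for di in (0, 1):
            wi = frac[:, 0] if di else 1.0 - frac[:, 0]
            ii = i0[:, 0] + di
            oki = (ii >= 0) & (ii < nx)
            for dj in (0, 1):
                wj = frac[:, 1] if dj else 1.0 - frac[:, 1]
                jj = i0[:, 1] + dj
                okj = (jj >= 0) & (jj < ny)
                for dk in (0, 1):
                    wk = frac[:, 2] if dk else 1.0 - frac[:, 2]
                    kk = i0[:, 2] + dk
                    ok = oki & okj & (kk >= 0) & (kk < nz)
                    w = wi * wj * wk
                    flat = (ii * ny + jj) * nz + kk
                    out_idx.append(np.where(ok, flat, 0))
                    out_w.append(np.where(ok, w, 0.0))
        return out_idx, out_w

    # -- matrix construction ----------------------------------------------

    def _build_matrix(self) -> sp.csr_matrix:
        n_rows = self.n_poses * self.n_pixels
        n_cols = self.grid.n_voxels
        mats = []
        for p, pose in enumerate(self.poses):
            R = _rotation_z(pose.gantry_angle_deg)
            rows_chunks, cols_chunks, vals_chunks = [], [], []
            for bundle in self._ray_geometry:
                if bundle is None:
                    continue
                pos, w, pix = self._samples(bundle)
                pos_w = pos @ R.T
                nb_idx, nb_w = self._trilinear(pos_w)
                base_row = p * self.n_pixels + pix
                for flat, ww in zip(nb_idx, nb_w):
                    nz = ww > 0
                    if not nz.any():
                        continue
                    rows_chunks.append(base_row[nz])
                    cols_chunks.append(flat[nz])
                    vals_chunks.append((w * ww)[nz])
            if rows_chunks:
                coo = sp.coo_matrix(
                    (
                        np.concatenate(vals_chunks),
                        (np.concatenate(rows_chunks), np.concatenate(cols_chunks)),
                    ),
                    shape=(n_rows, n_cols),
                )
                mats.append(coo.tocsr())
        if not mats:
            raise GeometryError("system operator is empty: no ray reaches the grid")
        G = mats[0]
        for m in mats[1:]:
            G = G + m
        return G

    # -- application -------------------------------------------------------

    def _blur(self, images: np.ndarray) -> np.ndarray:
        if self.blur_sigma_px <= 0:
            return images
        out = np.empty_like(images)
        for i in range(images.shape[0]):
            gaussian_filter(
                images[i], self.blur_sigma_px, mode="constant", cval=0.0, output=out[i]
            )
        return out

    def forward(self, values: np.ndarray) -> np.ndarray:
        """Project voxel activities to (n_poses, nu, nv) detector images."""
        x = np.asarray(values, dtype=float).ravel()
        if x.size != self.grid.n_voxels:
            raise GeometryError("volume does not match the operator grid")
        if self.G is not None:
            y = self.G @ x
        else:
            flat_vol = x
            y = np.zeros(self.n_poses * self.n_pixels)
            for p, pose in enumerate(self.poses):
                R = _rotation_z(pose.gantry_angle_deg)
                for bundle in self._ray_geometry:
                    if bundle is None:
                        continue
                    pos, w, pix = self._samples(bundle)
                    pos_w = pos @ R.T
                    nb_idx, nb_w = self._trilinear(pos_w)
                    sample_vals = np.zeros(len(w))
                    for flat, ww in zip(nb_idx, nb_w):
                        sample_vals += flat_vol[flat] * ww
                    contrib = np.bincount(
                        pix, weights=w * sample_vals, minlength=self.n_pixels
                    )
                    y[p * self.n_pixels : (p + 1) * self.n_pixels] += contrib
        images = y.reshape(self.n_poses, self.nu, self.nv)
        return self._blur(images)

    def adjoint(self, images: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`forward`; returns voxel values."""
        if self.G is None:
            raise GeometryError("adjoint requires a materialised operator")
        im = np.asarray(images, dtype=float)
        if im.shape != (self.n_poses, self.nu, self.nv):
            raise GeometryError("image stack does not match the operator geometry")
        yb = self._blur(im).ravel()
        return (self.G.T @ yb).reshape(self.grid.shape)

    def sensitivity_volume(self) -> np.ndarray:
        """Adjoint of all-ones images (the ML-EM normalisation term)."""
        ones = np.ones((self.n_poses, self.nu, self.nv))
        return self.adjoint(ones)


# ---------------------------------------------------------------------------
# Simulation pipeline
# ---------------------------------------------------------------------------

def _check_fov(volume: ActivityVolume, design: CollimatorDesign) -> None:
    x, y, z = volume.grid.voxel_centers()
    r2 = x**2 + y**2 + z**2
    outside = (r2 > design.fov_radius_mm**2) & (volume.values > 0)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} active voxel(s) lie outside the FOV sphere "
            "and are truncated by the projector",
            stacklevel=3,
        )


def forward_project(
    volume: ActivityVolume,
    design: CollimatorDesign,
    pose: DetectorPose,
    detector_pixel_mm: float | None = None,
) -> np.ndarray:
    """Noise-free detector image (nu, nv) of a volume at a single pose."""
    _check_fov(volume, design)
    op = SystemOperator(
        design, [pose], volume.grid, detector_pixel_mm=detector_pixel_mm, materialize=False
    )
    return op.forward(volume.values)[0]


def simulate_acquisition(
    volume: ActivityVolume,
    design: CollimatorDesign,
    orbit: Orbit,
    params: CountScalingParams | None = None,
    seed: int | None = None,
    detector_pixel_mm: float | None = None,
    operator: SystemOperator | None = None,
) -> ProjectionSet:
    """Full acquisition: project at every orbit pose, then optionally apply
    clinical count scaling and Poisson noise.

    A prebuilt ``operator`` (matching design/orbit/grid) may be supplied to
    amortise geometry across repeated simulations.
    """
    if operator is None:
        _check_fov(volume, design)
        operator = SystemOperator(
            design, orbit, volume.grid, detector_pixel_mm=detector_pixel_mm, materialize=False
        )
    images = operator.forward(volume.values)
    pset = ProjectionSet(
        images=images,
        orbit=orbit,
        design=design,
        detector_pixel_mm=operator.detector_pixel_mm,
        meta={"volume_label": volume.label},
    )
    if params is not None:
        pset = scale_counts(pset, params)
    if seed is not None:
        pset = add_poisson_noise(pset, seed)
    return pset


def scale_counts(pset: ProjectionSet, params: CountScalingParams) -> ProjectionSet:
    """Rescale noise-free projections to the clinical-equivalent total count."""
    if pset.total_counts <= 0:
        raise ScalingError("cannot scale projections with zero total counts")
    from .collimator import collimator_sensitivity

    n_p = params.n_p if params.n_p is not None else pset.orbit.n_projections
    s_mph = params.s_mph if params.s_mph is not None else collimator_sensitivity(pset.design)
    c_s = params.scaled_total(n_p=n_p, s_mph=s_mph)
    factor = c_s / pset.total_counts
    return pset.copy_with(
        pset.images * factor,
        scaled_total=c_s,
        c_ref=params.c_ref,
        n_p=n_p,
        s_mph=s_mph,
        n_ref=params.n_ref,
        s_lehr=params.s_lehr,
    )


def add_poisson_noise(pset: ProjectionSet, seed: int) -> ProjectionSet:
    """Replace each pixel by a Poisson draw with that pixel's mean."""
    if np.any(pset.images < 0):
        raise ValueError("projection means must be nonnegative")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(pset.images).astype(float)
    return pset.copy_with(noisy, noise_seed=int(seed))
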