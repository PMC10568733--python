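"""Maximum-likelihood expectation-maximisation reconstruction.

:class:`MLEMModel` treats the projection data as independent Poisson counts
with mean ``A x`` (``A`` the system operator of :mod:`mphspect.projector`,
``x`` the nonnegative voxel activities) and fits ``x`` by the multiplicative
EM update

    x_{n+1} = x_n / s * A^T( y / (A x_n) ),    s = A^T 1,

starting from a uniform positive image inside the imaged support. The
update preserves nonnegativity, never decreases the Poisson log-likelihood,
and satisfies the count-preservation identity ``sum(s * x_{n+1}) = sum(y)``;
all three are tracked as fit diagnostics. Voxels with zero sensitivity are
frozen at zero so that the 0/0 ratio never occurs.

No regularisation, subsets or post-filtering are applied: image quality is
controlled purely by the iteration number, which is why the evaluation
metrics are reported per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collimator import CollimatorDesign, Orbit
from .errors import DegenerateDataError, GeometryError
from .grids import ActivityVolume, VoxelGrid
from .projector import ProjectionSet, SystemOperator

__all__ = [
    "ReconConfig",
    "MLEMModel",
    "MLEMResults",
    "mlem",
    "reconstruct_2d",
    "back_project",
    "sensitivity_image",
]


def default_recon_grid() -> VoxelGrid:
    """Full-scale reconstruction grid: 200^3 voxels of 3.125 mm."""
    return VoxelGrid.centered(200, 3.125)


def default_crop_grid() -> VoxelGrid:
    return VoxelGrid.centered(64, 3.125)


@dataclass
class ReconConfig:
    """Reconstruction settings.

    The reconstruction grid is deliberately larger than the phantom so that
    activity near the FOV edge is not truncated; the result is cropped back
    to ``crop_grid`` (centred, same voxel size) for analysis. Smaller
    matched grids can be configured for quick studies.
    """

    n_iterations: int = 40
    recon_grid: VoxelGrid | None = None
    crop_grid: VoxelGrid | None = None
    init_value: float = 1.0
    save_every: int | None = None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.init_value <= 0:
            raise ValueError("init_value must be positive")
        if self.recon_grid is None:
            self.recon_grid = default_recon_grid()
        if self.crop_grid is None:
            if self.recon_grid.shape[2] == 1:
                n = min(64, self.recon_grid.shape[0])
                self.crop_grid = VoxelGrid.centered(
                    (n, n, 1), self.recon_grid.voxel_size_mm
                )
            else:
                n = min(64, self.recon_grid.shape[0])
                self.crop_grid = VoxelGrid.centered(n, self.recon_grid.voxel_size_mm)
        for a in range(3):
            if self.crop_grid.shape[a] > self.recon_grid.shape[a]:
                raise ValueError("crop grid must fit inside the recon grid")


def _center_crop(values: np.ndarray, recon_grid: VoxelGrid, crop_grid: VoxelGrid) -> np.ndarray:
    if recon_grid.voxel_size_mm != crop_grid.voxel_size_mm:
        raise ValueError("crop grid must share the recon voxel size")
    slices = []
    for a in range(3):
        off = (recon_grid.shape[a] - crop_grid.shape[a]) // 2
        slices.append(slice(off, off + crop_grid.shape[a]))
    return values[tuple(slices)]


class MLEMModel:
    """Poisson emission model for a multi-pinhole projection data set.

    Parameters
    ----------
    projections
        Measured (or simulated) projection set.
    config
        Reconstruction settings; defaults to the full-scale grid.
    operator
        Optional prebuilt system operator on ``config.recon_grid`` matching
        the projection geometry, to amortise setup across fits.
    """

    def __init__(
        self,
        projections: ProjectionSet,
        config: ReconConfig | None = None,
        operator: SystemOperator | None = None,
    ) -> None:
        if projections.design.family not in {"MPGP", "MPHR"}:
            raise ValueError("only multi-pinhole (MPGP/MPHR) designs are supported")
        if projections.images.sum() <= 0:
            raise DegenerateDataError("all-zero projections admit no reconstruction")
        self.projections = projections
        self.config = config if config is not None else ReconConfig()
        if operator is None:
            operator = SystemOperator(
                projections.design,
                projections.orbit,
                self.config.recon_grid,
                detector_pixel_mm=projections.detector_pixel_mm,
                materialize=True,
            )
        else:
            if operator.grid != self.config.recon_grid:
                raise GeometryError("operator grid does not match the recon grid")
            if operator.n_poses != projections.orbit.n_projections:
                raise GeometryError("operator poses do not match the orbit")
        if (operator.n_poses, operator.nu, operator.nv) != projections.images.shape:
            raise GeometryError("projection images do not match the operator geometry")
        self.operator = operator
        sens = operator.sensitivity_volume()
        self._sens = sens
        self._support = sens > 1e-12 * sens.max()

    def fit(
        self,
        n_iterations: int | None = None,
        callback=None,
    ) -> "MLEMResults":
        """Run EM updates and return a results object.

        ``callback(iteration, volume_values)`` is invoked after every
        iteration and may be used for per-iteration metric tracking.
        """
        cfg = self.config
        n_iter = cfg.n_iterations if n_iterations is None else int(n_iterations)
        op = self.operator
        y = self.projections.images
        y_flat_sum = float(y.sum())
        s = np.where(self._support, self._sens, 1.0)

        x = np.where(self._support, cfg.init_value, 0.0).astype(float)
        loglike = np.empty(n_iter)
        count_ratio = np.empty(n_iter)
        snapshots: list[np.ndarray] = []
        for it in range(n_iter):
            y_hat = op.forward(x)
            pos = y_hat > 0
            ratio = np.zeros_like(y_hat)
            ratio[pos] = y[pos] / y_hat[pos]
            x = x / s * op.adjoint(ratio)
            x[~self._support] = 0.0
            with np.errstate(divide="ignore"):
                ll = float(np.sum(y[pos] * np.log(y_hat[pos])) - y_hat.sum())
            loglike[it] = ll
            count_ratio[it] = float((self._sens * x).sum()) / y_flat_sum
            if cfg.save_every and (it + 1) % cfg.save_every == 0:
                snapshots.append(x.copy())
            if callback is not None:
                callback(it + 1, x)
        cropped = _center_crop(x, cfg.recon_grid, cfg.crop_grid)
        return MLEMResults(
            model=self,
            volume=ActivityVolume(cfg.crop_grid, cropped, label="mlem-recon"),
            full_volume=ActivityVolume(cfg.recon_grid, x, label="mlem-recon-full"),
            log_likelihood_trace=loglike,
            count_preservation_trace=count_ratio,
            iteration_snapshots=snapshots,
            n_iterations=n_iter,
        )


@dataclass
class MLEMResults:
    """Fitted activity estimate with convergence diagnostics."""

    model: MLEMModel
    volume: ActivityVolume
    full_volume: ActivityVolume
    log_likelihood_trace: np.ndarray
    count_preservation_trace: np.ndarray
    n_iterations: int
    iteration_snapshots: list = field(default_factory=list)

    @property
    def config(self) -> ReconConfig:
        return self.model.config

    def summary(self) -> str:
        ll = self.log_likelihood_trace
        monotone = bool(np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1])))
        cp_dev = float(np.abs(self.count_preservation_trace - 1.0).max())
        lines = [
            "ML-EM Reconstruction Results",
            "=" * 34,
            f"projections:        {self.model.projections.orbit.n_projections}"
            f" ({self.model.projections.orbit.mode}-mode)",
            f"pinholes:           {self.model.projections.design.n_pinholes}"
            f" ({self.model.projections.design.family})",
            f"iterations:         {self.n_iterations}",
            f"recon grid:         {self.config.recon_grid.shape}"
            f" @ {self.config.recon_grid.voxel_size_mm[0]:g} mm",
            f"crop grid:          {self.config.crop_grid.shape}",
            f"data counts:        {self.model.projections.total_counts:.6g}",
            f"final log-like:     {ll[-1]:.6g}",
            f"monotone ascent:    {monotone}",
            f"max |count ratio-1|: {cp_dev:.3g}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def mlem(
    projections: ProjectionSet,
    design: CollimatorDesign | None = None,
    orbit: Orbit | None = None,
    config: ReconConfig | None = None,
) -> MLEMResults:
    """Reconstruct a projection set (volumetric)."""
    if design is not None and design is not projections.design:
        raise GeometryError("design does not match the projection set")
    if orbit is not None and orbit is not projections.orbit:
        raise GeometryError("orbit does not match the projection set")
    return MLEMModel(projections, config=config).fit()


def reconstruct_2d(
    projections: ProjectionSet,
    design: CollimatorDesign | None = None,
    orbit: Orbit | None = None,
    config: ReconConfig | None = None,
) -> MLEMResults:
    """Reconstruct a single-slice (2D phantom) acquisition."""
    if config is None:
        grid = VoxelGrid.centered((64, 64, 1), (3.125, 3.125, 3.125))
        config = ReconConfig(n_iterations=40, recon_grid=grid, crop_grid=grid)
    if config.recon_grid.shape[2] != 1:
        raise ValueError("reconstruct_2d requires a single-slice recon grid")
    return mlem(projections, design, orbit, config)


def back_project(
    images: np.ndarray | ProjectionSet,
    design: CollimatorDesign,
    orbit: Orbit,
    grid: VoxelGrid | None = None,
    detector_pixel_mm: float | None = None,
) -> ActivityVolume:
    """Apply the exact adjoint of the forward projector, A^T y."""
    if isinstance(images, ProjectionSet):
        detector_pixel_mm = images.detector_pixel_mm
        images = images.images
    if grid is None:
        grid = default_crop_grid()
    op = SystemOperator(design, orbit, grid, detector_pixel_mm=detector_pixel_mm)
    values = op.adjoint(np.asarray(images, dtype=float))
    return ActivityVolume(grid, values, label="backprojection")


def sensitivity_image(
    design: CollimatorDesign,
    orbit: Orbit,
    grid: VoxelGrid | None = None,
    detector_pixel_mm: float | None = None,
) -> ActivityVolume:
    """A^T 1 over all poses and pinholes (the ML-EM normaliser)."""
    if grid is None:
        grid = default_crop_grid()
    op = SystemOperator(design, orbit, grid, detector_pixel_mm=detector_pixel_mm)
    return ActivityVolume(grid, op.sensitivity_volume(), label="sensitivity")
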