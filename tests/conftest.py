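import numpy as np
import pytest

from mphspect import DetectorPose, design_collimator, make_orbit
from mphspect.grids import VoxelGrid


@pytest.fixture(scope="session")
def mpgp9():
    return design_collimator("MPGP", 9)


@pytest.fixture(scope="session")
def mpgp1():
    return design_collimator("MPGP", 1)


@pytest.fixture(scope="session")
def mphr9():
    return design_collimator("MPHR", 9)


@pytest.fixture(scope="session")
def small_grid():
    """16^3 grid spanning the FOV (coarse, for operator tests)."""
    return VoxelGrid.centered(16, 12.5)


@pytest.fixture(scope="session")
def orbit8():
    return make_orbit(8, "H")


def measure_point_source_fwhm(design, pinhole_index: int | None = None) -> float:
    """Object-space FWHM (mm) of a point source imaged through the projector.

    The source sits at the radius of rotation from the chosen aperture along
    its axis; the detector blob's FWHM is read off an interpolated profile
    and mapped back to object space through the pinhole magnification.
    """
    from mphspect.grids import ActivityVolume
    from mphspect.projector import SystemOperator

    if pinhole_index is None:
        # the pinhole closest to the plate centre
        offs = [np.hypot(*ph.plate_position_mm) for ph in design.pinholes]
        pinhole_index = int(np.argmin(offs))
    ph = design.pinholes[pinhole_index]
    aperture = design.aperture_positions()[pinhole_index]
    tilt = np.asarray(ph.tilt)
    src = aperture + design.ror_mm * tilt  # ror mm from the aperture, on-axis

    grid = VoxelGrid(
        shape=(9, 9, 9), voxel_size_mm=(1.0, 1.0, 1.0),
        origin_mm=tuple(src - 4.0),
    )
    vol = np.zeros((9, 9, 9))
    vol[4, 4, 4] = 1.0
    px = 0.8
    op = SystemOperator(design, [DetectorPose(0.0)], grid,
                        detector_pixel_mm=px, materialize=False)
    img = op.forward(ActivityVolume(grid, vol, "point").values)[0]

    # expected blob centre: ray from source through the aperture
    x_det = design.ror_mm + design.focal_length_mm
    t_par = (x_det - src[0]) / (aperture[0] - src[0])
    blob = src + t_par * (aperture - src)
    iu = int(round(blob[1] / px + (op.nu - 1) / 2.0))
    iv = int(round(blob[2] / px + (op.nv - 1) / 2.0))
    w = 40
    sub = img[max(iu - w, 0): iu + w, max(iv - w, 0): iv + w]
    ju, jv = np.unravel_index(np.argmax(sub), sub.shape)
    prof = sub[:, jv]
    half = prof.max() / 2.0
    above = np.where(prof >= half)[0]
    i0, i1 = above[0], above[-1]
    xl = (i0 - 1) + (half - prof[i0 - 1]) / (prof[i0] - prof[i0 - 1])
    xr = i1 + (prof[i1] - half) / (prof[i1] - prof[i1 + 1])
    fwhm_det = (xr - xl) * px
    magnification = design.focal_length_mm / design.ror_mm
    return fwhm_det / magnification
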