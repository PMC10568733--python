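import numpy as np
import pytest

from mphspect import (
    ActivityVolume,
    CollimatorDesign,
    DegenerateDataError,
    MLEMModel,
    ReconConfig,
    back_project,
    make_orbit,
    make_star,
    nmse,
    reconstruct_2d,
    sensitivity_image,
    simulate_acquisition,
)
from mphspect.grids import VoxelGrid
from mphspect.projector import ProjectionSet, SystemOperator


@pytest.fixture(scope="module")
def setup16(mpgp9, small_grid):
    orbit = make_orbit(8, "H")
    op = SystemOperator(mpgp9, orbit, small_grid, detector_pixel_mm=6.4)
    x, y, z = small_grid.voxel_centers()
    vals = np.exp(-((x / 40) ** 2 + (y / 50) ** 2 + (z / 35) ** 2))
    vals[x**2 + y**2 + z**2 > 95.0**2] = 0.0
    truth = ActivityVolume(small_grid, vals, "blob")
    return orbit, op, truth


def _pset(images, orbit, design):
    return ProjectionSet(images=images, orbit=orbit, design=design,
                         detector_pixel_mm=6.4)


class TestEMProperties:
    def test_uniform_fixed_point(self, mpgp9, small_grid, setup16):
        orbit, op, _ = setup16
        support = op.sensitivity_volume() > 0
        uniform = np.where(support, 1.0, 0.0)
        y = op.forward(uniform)
        cfg = ReconConfig(n_iterations=1, recon_grid=small_grid, crop_grid=small_grid)
        model = MLEMModel(_pset(y, orbit, mpgp9), config=cfg, operator=op)
        res = model.fit()
        x1 = res.full_volume.values
        assert np.max(np.abs(x1[support] - uniform[support])) < 1e-6

    def test_monotone_likelihood_and_count_preservation(self, mpgp9, small_grid, setup16):
        orbit, op, truth = setup16
        rng = np.random.default_rng(1)
        y = rng.poisson(op.forward(truth.values) * 2e4).astype(float)
        cfg = ReconConfig(n_iterations=25, recon_grid=small_grid, crop_grid=small_grid)
        res = MLEMModel(_pset(y, orbit, mpgp9), config=cfg, operator=op).fit()
        ll = res.log_likelihood_trace
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))
        assert np.all(np.abs(res.count_preservation_trace - 1.0) <= 1e-4)
        assert np.all(res.full_volume.values >= 0)

    def test_deterministic(self, mpgp9, small_grid, setup16):
        orbit, op, truth = setup16
        y = op.forward(truth.values)
        cfg = ReconConfig(n_iterations=5, recon_grid=small_grid, crop_grid=small_grid)
        a = MLEMModel(_pset(y, orbit, mpgp9), config=cfg, operator=op).fit()
        b = MLEMModel(_pset(y, orbit, mpgp9), config=cfg, operator=op).fit()
        np.testing.assert_array_equal(a.volume.values, b.volume.values)

    def test_all_zero_projections_rejected(self, mpgp9, small_grid, setup16):
        orbit, op, _ = setup16
        with pytest.raises(DegenerateDataError):
            MLEMModel(_pset(np.zeros((op.n_poses, op.nu, op.nv)), orbit, mpgp9))

    def test_noise_free_self_consistency(self, mpgp9, small_grid, setup16):
        """Noise-free data of a smooth phantom reconstructs to low masked NMSE."""
        orbit, op, truth = setup16
        y = op.forward(truth.values)
        cfg = ReconConfig(n_iterations=100, recon_grid=small_grid, crop_grid=small_grid)
        res = MLEMModel(_pset(y, orbit, mpgp9), config=cfg, operator=op).fit()
        mask = truth.values > 0.05 * truth.values.max()
        x = res.full_volume.values
        x = x * truth.values[mask].sum() / x[mask].sum()
        assert nmse(x, truth.values, mask) < 0.05

    def test_summary_mentions_key_facts(self, mpgp9, small_grid, setup16):
        orbit, op, truth = setup16
        y = op.forward(truth.values)
        cfg = ReconConfig(n_iterations=3, recon_grid=small_grid, crop_grid=small_grid)
        res = MLEMModel(_pset(y, orbit, mpgp9), config=cfg, operator=op).fit()
        s = res.summary()
        assert "iterations:         3" in s and "MPGP" in s


class TestBackProjection:
    def test_zero_images(self, mpgp9, small_grid, setup16):
        orbit, op, _ = setup16
        vol = back_project(np.zeros((op.n_poses, op.nu, op.nv)), mpgp9, orbit,
                           grid=small_grid, detector_pixel_mm=6.4)
        assert np.all(vol.values == 0)

    def test_uniform_images_positive_inside_fov(self, mpgp9, small_grid, setup16):
        orbit, op, _ = setup16
        vol = back_project(np.ones((op.n_poses, op.nu, op.nv)), mpgp9, orbit,
                           grid=small_grid, detector_pixel_mm=6.4)
        x, y, z = small_grid.voxel_centers()
        interior = x**2 + y**2 + z**2 < (0.9 * mpgp9.fov_radius_mm) ** 2
        assert np.all(vol.values[interior] > 0)

    def test_sensitivity_linear_in_poses(self, mpgp9, small_grid):
        s2 = sensitivity_image(mpgp9, make_orbit(2, "H"), grid=small_grid,
                               detector_pixel_mm=6.4)
        s4 = sensitivity_image(mpgp9, make_orbit(4, "H"), grid=small_grid,
                               detector_pixel_mm=6.4)
        c = small_grid.shape[0] // 2
        center2 = s2.values[c - 1 : c + 1, c - 1 : c + 1, c - 1 : c + 1].mean()
        center4 = s4.values[c - 1 : c + 1, c - 1 : c + 1, c - 1 : c + 1].mean()
        assert center4 / center2 == pytest.approx(2.0, rel=0.02)

    def test_outside_acceptance_zero(self, mpgp1, small_grid):
        s = sensitivity_image(mpgp1, make_orbit(2, "H"), grid=small_grid,
                              detector_pixel_mm=6.4)
        # voxels beyond the FOV sphere (plus one voxel of trilinear reach)
        # are never traversed
        x, y, z = small_grid.voxel_centers()
        margin = np.sqrt(3.0) * max(small_grid.voxel_size_mm)
        outside = x**2 + y**2 + z**2 > (mpgp1.fov_radius_mm + margin) ** 2
        assert np.all(s.values[outside] == 0)


class TestReconstruct2D:
    def test_star_converges_with_iterations(self, mpgp9):
        star = make_star()
        orbit = make_orbit(32, "H")
        pset = simulate_acquisition(star, mpgp9, orbit, detector_pixel_mm=3.2)
        cfg5 = ReconConfig(n_iterations=5, recon_grid=star.grid, crop_grid=star.grid)
        cfg40 = ReconConfig(n_iterations=40, recon_grid=star.grid, crop_grid=star.grid)
        op = SystemOperator(mpgp9, orbit, star.grid, detector_pixel_mm=3.2)
        r5 = MLEMModel(pset, config=cfg5, operator=op).fit()
        r40 = MLEMModel(pset, config=cfg40, operator=op).fit()

        x, y, _ = star.grid.voxel_centers()
        mask = (x**2 + y**2) <= 100.0**2

        def scaled_nmse(res):
            v = res.volume.values
            v = v * star.values[mask].sum() / v[mask].sum()
            return nmse(v, star.values, mask)

        assert scaled_nmse(r40) < scaled_nmse(r5)

    def test_requires_single_slice(self, mpgp9, small_grid, setup16):
        orbit, op, truth = setup16
        pset = _pset(op.forward(truth.values), orbit, mpgp9)
        cfg = ReconConfig(n_iterations=2, recon_grid=small_grid, crop_grid=small_grid)
        with pytest.raises(ValueError):
            reconstruct_2d(pset, config=cfg)

    def test_non_pinhole_family_rejected(self):
        with pytest.raises(ValueError):
            CollimatorDesign(family="LEHR", target_resolution_mm=12.0, n_pinholes=1,
                             pinholes=(), focal_length_mm=100.0)


class TestCrop:
    def test_center_crop_alignment(self, mpgp9):
        recon_grid = VoxelGrid.centered(20, 10.0)
        crop_grid = VoxelGrid.centered(10, 10.0)
        orbit = make_orbit(2, "H")
        op = SystemOperator(mpgp9, orbit, recon_grid, detector_pixel_mm=6.4)
        vals = np.zeros(recon_grid.shape)
        vals[10, 10, 10] = 5.0
        y = op.forward(vals) + 1e-3
        cfg = ReconConfig(n_iterations=1, recon_grid=recon_grid, crop_grid=crop_grid)
        res = MLEMModel(ProjectionSet(images=y, orbit=orbit, design=mpgp9,
                                      detector_pixel_mm=6.4), config=cfg, operator=op).fit()
        assert res.volume.grid.shape == (10, 10, 10)
        np.testing.assert_array_equal(
            res.volume.values, res.full_volume.values[5:15, 5:15, 5:15]
        )
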