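import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

from mphspect import (
    ActivityVolume,
    BrainPhantomSpec,
    UndefinedMetricError,
    circular_profile,
    cov,
    extract_profile,
    make_brain_phantom,
    make_derenzo,
    nmse,
    sbr,
    sbr_error,
    smallest_resolved_rod,
    star_bar_count,
    make_star,
)
from mphspect.grids import RegionMask, VoxelGrid


@pytest.fixture(scope="module")
def trodat():
    return make_brain_phantom(BrainPhantomSpec(tracer="TRODAT"))


class TestNmse:
    def test_identities(self, trodat):
        vol, masks = trodat
        mask = masks["whole_brain"]
        assert nmse(vol, vol, mask) == 0.0
        assert nmse(np.zeros_like(vol.values), vol.values, mask) == 1.0
        assert nmse(2.0 * vol.values, vol.values, mask) == pytest.approx(1.0, abs=0)

    def test_zero_truth_energy_rejected(self, trodat):
        vol, masks = trodat
        with pytest.raises(UndefinedMetricError):
            nmse(vol.values, np.zeros_like(vol.values), masks["whole_brain"])

    def test_permutation_invariance(self, trodat):
        vol, masks = trodat
        rng = np.random.default_rng(0)
        recon = vol.values + rng.normal(0, 0.1, vol.values.shape)
        recon = np.abs(recon)
        mask = masks["striatum_box"].member
        base = nmse(recon, vol.values, mask)
        perm = rng.permutation(vol.values.size)
        shape = vol.values.shape
        assert nmse(
            recon.ravel()[perm].reshape(shape),
            vol.values.ravel()[perm].reshape(shape),
            mask.ravel()[perm].reshape(shape),
        ) == pytest.approx(base, rel=1e-12)

    def test_single_pass_oracle(self, trodat):
        vol, masks = trodat
        rng = np.random.default_rng(1)
        recon = np.abs(vol.values + rng.normal(0, 0.2, vol.values.shape))
        m = masks["whole_brain"].member
        # naive loop-free oracle written independently of the implementation
        num = float(((recon[m] - vol.values[m]) ** 2).sum())
        den = float((vol.values[m] ** 2).sum())
        assert nmse(recon, vol.values, m) == pytest.approx(num / den, rel=1e-12)


class TestSbr:
    def test_ground_truth_value(self, trodat):
        vol, masks = trodat
        assert sbr(vol, masks["striatum"], masks["background_voi"]) == 9.0
        assert sbr_error(vol, masks["striatum"], masks["background_voi"]) == 0.0

    def test_simple_ratios(self, trodat):
        _, masks = trodat
        grid = masks["striatum"].grid
        v = np.ones(grid.shape)
        v[masks["striatum"].member] = 10.0
        assert sbr(v, masks["striatum"], masks["background_voi"]) == pytest.approx(9.0)
        assert sbr(np.ones(grid.shape), masks["striatum"], masks["background_voi"]) == 0.0
        v[masks["striatum"].member] = 9.0
        assert sbr_error(v, masks["striatum"], masks["background_voi"]) == pytest.approx(1.0)


class TestCov:
    def test_constant_region(self, trodat):
        vol, masks = trodat
        assert cov(np.full(vol.values.shape, 3.0), masks["background_voi"]) == 0.0

    def test_default_voi_size(self, trodat):
        _, masks = trodat
        assert masks["background_voi"].n_voxels == 630

    def test_closed_form_oracle(self, trodat):
        _, masks = trodat
        rng = np.random.default_rng(2)
        voi = masks["background_voi"]
        v = np.ones(voi.grid.shape)
        draws = rng.normal(10.0, 2.0, voi.n_voxels)
        v[voi.member] = draws
        expected = draws.std(ddof=1) / draws.mean()
        assert cov(v, voi) == pytest.approx(expected, rel=1e-12)
        # large-sample value approaches sigma/mu
        assert cov(v, voi) == pytest.approx(0.2, rel=0.1)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e6),
           seed=st.integers(min_value=0, max_value=2**16))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        grid = VoxelGrid.centered(8, 10.0)
        member = np.zeros(grid.shape, dtype=bool)
        member[2:6, 2:6, 2:6] = True
        voi = RegionMask(grid, member, "background_voi")
        v = np.abs(rng.normal(5.0, 1.0, grid.shape)) + 0.1
        assert cov(scale * v, voi) == pytest.approx(cov(v, voi), rel=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(gain=st.floats(min_value=0.1, max_value=100.0))
    def test_sbr_invariant_under_gain(self, gain, trodat):
        # SBR is a ratio metric: a global intensity gain leaves it unchanged
        vol, masks = trodat
        base = sbr(vol, masks["striatum"], masks["background_voi"])
        assert sbr(gain * vol.values, masks["striatum"],
                   masks["background_voi"]) == pytest.approx(base, rel=1e-9)


class TestProfiles:
    def test_uniform_region_constant(self):
        grid = VoxelGrid.centered((64, 64, 1), (3.125, 3.125, 3.125))
        vol = ActivityVolume(grid, np.full(grid.shape, 4.0))
        prof = extract_profile(vol, (-50.0, 0.0), (50.0, 0.0), n_samples=100)
        assert np.allclose(prof.values, 4.0)

    def test_profile_across_rod_width(self):
        from mphspect.phantoms import derenzo_rod_centers, DEFAULT_ROD_DIAMETERS_MM

        fine = VoxelGrid.centered((256, 256, 1), (0.78125, 0.78125, 3.125))
        vol = make_derenzo(grid=fine)
        sectors = derenzo_rod_centers()
        d = DEFAULT_ROD_DIAMETERS_MM[-1]  # 12.7 mm rods
        c = sectors[-1][0]
        # window of one diameter around the rod: neighbours sit 2d away
        prof = extract_profile(vol, (c[0] - d, c[1]), (c[0] + d, c[1]),
                               n_samples=800)
        width = np.sum(prof.values >= 0.5) * (prof.positions_mm[1] - prof.positions_mm[0])
        assert width == pytest.approx(d, abs=2.0)

    def test_star_alternation_count(self):
        vol = make_star()
        prof = circular_profile(vol, 60.0, n_samples=3600)
        above = prof.values > 0.5
        assert int(np.sum(above != np.roll(above, 1))) == 32

    def test_endpoint_outside_rejected(self):
        grid = VoxelGrid.centered((64, 64, 1), (3.125, 3.125, 3.125))
        vol = ActivityVolume(grid, np.ones(grid.shape))
        with pytest.raises(ValueError):
            extract_profile(vol, (0.0, 0.0), (500.0, 0.0))


class TestResolvedRod:
    def test_ground_truth_fully_resolved(self):
        vol = make_derenzo()
        assert smallest_resolved_rod(vol) == 4.8

    def test_heavy_blur_unresolved(self):
        vol = make_derenzo()
        fwhm_vox = 2 * 12.7 / 3.125
        blurred = gaussian_filter(vol.values, fwhm_vox / 2.3548)
        assert smallest_resolved_rod(vol.copy_with(blurred)) is None

    def test_monotone_under_blur(self):
        vol = make_derenzo()
        results = []
        for fwhm_mm in (0.0, 4.0, 8.0, 16.0, 32.0):
            sigma = fwhm_mm / 2.3548 / 3.125
            v = gaussian_filter(vol.values, sigma) if sigma else vol.values
            r = smallest_resolved_rod(vol.copy_with(v))
            results.append(np.inf if r is None else r)
        assert all(a <= b for a, b in zip(results, results[1:]))


class TestStarBars:
    def test_truth_counts(self):
        vol = make_star()
        for r in (40.0, 60.0, 80.0):
            assert star_bar_count(vol, r) == 16

    def test_washed_out_pattern(self):
        grid = VoxelGrid.centered((64, 64, 1), (3.125, 3.125, 3.125))
        vol = ActivityVolume(grid, np.full(grid.shape, 2.0))
        assert star_bar_count(vol, 50.0) == 0
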