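"""Motion-correction and z-motion tests, including brute-force oracles."""

import numpy as np
import pytest

from cannulascope import motion, synth
from _oracles import dense_shift_search


@pytest.fixture(scope="module")
def single_patch_grid():
    return motion.PatchGrid((128, 128), (128, 128), (32, 32))


class TestPatchGrid:
    def test_stride_must_not_exceed_patch(self):
        with pytest.raises(ValueError):
            motion.PatchGrid((64, 64), (96, 96))

    def test_slices_cover_frame(self):
        grid = motion.PatchGrid((128, 128), (64, 64))
        slices = grid.patch_slices((256, 320))
        cover = np.zeros((256, 320), dtype=bool)
        for sy, sx in slices:
            cover[sy, sx] = True
        assert cover.all()

    def test_centers_form_regular_grid(self):
        grid = motion.PatchGrid((128, 128), (64, 64))
        centers = grid.patch_centers((256, 256))
        assert len(centers) == 9


class TestEstimateTemplate:
    def test_identical_frames_give_that_frame(self, textured_image):
        movie = np.stack([textured_image] * 5)
        tpl = motion.estimate_template(movie, n_frames=5, n_iter=2)
        np.testing.assert_allclose(tpl, textured_image, rtol=1e-10)

    def test_zero_iterations_is_plain_mean(self, textured_image):
        movie = np.stack([textured_image, 2 * textured_image])
        tpl = motion.estimate_template(movie, n_frames=2, n_iter=0)
        np.testing.assert_allclose(tpl, 1.5 * textured_image)

    def test_registered_mean_converges_to_consensus_scene(self, textured_image):
        # frames shifted symmetrically about zero: the iterated
        # mean-of-registered-frames template sharpens to the zero-shift
        # scene (the consensus position), unlike the blurred plain mean
        movie = np.stack(
            [
                np.roll(textured_image, (4, -3), axis=(0, 1)),
                textured_image,
                np.roll(textured_image, (-4, 3), axis=(0, 1)),
            ]
        )
        tpl = motion.estimate_template(movie, n_frames=3, n_iter=4)
        interior = (slice(10, -10), slice(10, -10))
        rms = np.sqrt(np.mean((tpl[interior] - textured_image[interior]) ** 2))
        plain = movie.mean(axis=0)
        rms_plain = np.sqrt(np.mean((plain[interior] - textured_image[interior]) ** 2))
        assert rms < 0.5 * rms_plain
        assert rms / textured_image[interior].std() < 0.25

    def test_empty_movie_raises(self):
        with pytest.raises(ValueError):
            motion.estimate_template(np.zeros((0, 8, 8)))


class TestEstimatePatchShifts:
    def test_integer_shift_exact(self, textured_image, single_patch_grid):
        frame = np.roll(textured_image, (3, -2), axis=(0, 1))
        s, _ = motion.estimate_patch_shifts(frame, textured_image, single_patch_grid)
        np.testing.assert_array_equal(s[0], [3, -2])

    def test_zero_shift_exact(self, textured_image, single_patch_grid):
        s, _ = motion.estimate_patch_shifts(
            textured_image, textured_image, single_patch_grid
        )
        np.testing.assert_array_equal(s[0], [0, 0])

    def test_subpixel_shift_matches_brute_force_oracle(self, single_patch_grid):
        rng = np.random.default_rng(5)
        from scipy import ndimage
        tpl = ndimage.gaussian_filter(rng.random((128, 128)), 2)
        from scipy.ndimage import fourier_shift
        frame = np.real(np.fft.ifft2(fourier_shift(np.fft.fft2(tpl), (1.5, 0))))
        s, _ = motion.estimate_patch_shifts(
            frame, tpl, single_patch_grid, upsample_factor=10
        )
        assert abs(s[0][0] - 1.5) <= 0.1
        oracle = dense_shift_search(tpl, frame, (1.2, 1.8), (-0.2, 0.25), step=0.05)
        assert np.all(np.abs(s[0] - oracle) <= 0.1)

    def test_flat_patch_flagged_not_raised(self, single_patch_grid):
        flat = np.zeros((128, 128))
        s, c = motion.estimate_patch_shifts(flat, flat, single_patch_grid)
        np.testing.assert_array_equal(s[0], [0, 0])
        assert c[0] == 0.0

    def test_shift_clipped_to_max(self, textured_image, single_patch_grid):
        frame = np.roll(textured_image, (8, 0), axis=(0, 1))
        s, _ = motion.estimate_patch_shifts(
            frame, textured_image, single_patch_grid, max_shift_px=5
        )
        assert np.abs(s).max() <= 5


class TestInterpolateMotionField:
    def test_uniform_shift_gives_constant_field(self):
        centers = np.array([[10.0, 10.0], [10.0, 50.0], [50.0, 10.0], [50.0, 50.0]])
        shifts = np.tile([2.0, -1.0], (4, 1))
        field = motion.interpolate_motion_field(shifts, centers, (64, 64))
        np.testing.assert_allclose(field[..., 0], 2.0)
        np.testing.assert_allclose(field[..., 1], -1.0)

    def test_midpoint_linearity(self):
        centers = np.array([[16.0, 8.0], [16.0, 40.0]])
        shifts = np.array([[0.0, 0.0], [0.0, 2.0]])
        field = motion.interpolate_motion_field(shifts, centers, (32, 48))
        assert field[16, 24, 1] == pytest.approx(1.0)

    def test_field_at_centers_equals_inputs(self):
        rng = np.random.default_rng(0)
        ys = [8.0, 24.0, 40.0]
        xs = [8.0, 24.0, 40.0]
        centers = np.array([[y, x] for y in ys for x in xs])
        shifts = rng.normal(size=(9, 2))
        field = motion.interpolate_motion_field(shifts, centers, (48, 48))
        for (y, x), s in zip(centers, shifts):
            np.testing.assert_allclose(field[int(y), int(x)], s, atol=1e-12)

    def test_nan_shifts_raise(self):
        centers = np.array([[8.0, 8.0]])
        with pytest.raises(ValueError):
            motion.interpolate_motion_field(np.array([[np.nan, 0.0]]), centers, (16, 16))


class TestApplyMotionField:
    def test_zero_field_bit_identical(self, textured_image):
        out = motion.apply_motion_field(textured_image, np.zeros((128, 128, 2)))
        assert np.array_equal(out, textured_image)

    def test_constant_integer_field_shifts_columns(self, textured_image):
        field = np.zeros((128, 128, 2))
        field[..., 1] = 5.0
        out = motion.apply_motion_field(textured_image, field)
        np.testing.assert_allclose(out[:, :-5], textured_image[:, 5:], rtol=1e-12)

    def test_round_trip_small_residual(self, textured_image):
        rng = np.random.default_rng(3)
        from scipy import ndimage
        field = np.stack(
            [ndimage.gaussian_filter(rng.normal(0, 2, (128, 128)), 20)] * 2, axis=-1
        )
        warped = motion.apply_motion_field(textured_image, field)
        back = motion.apply_motion_field(warped, -field)
        interior = (slice(12, -12), slice(12, -12))
        rms = np.sqrt(np.mean((back[interior] - textured_image[interior]) ** 2))
        assert rms / np.sqrt(np.mean(textured_image[interior] ** 2)) < 0.02

    def test_huge_field_raises(self, textured_image):
        field = np.full((128, 128, 2), 500.0)
        with pytest.raises(ValueError):
            motion.apply_motion_field(textured_image, field)


class TestDisplacementSummaries:
    @pytest.mark.parametrize(
        "shifts,expected",
        [
            ([[1, 0], [-3, 2]], [-3, 2]),
            ([[0, 0]], [0, 0]),
            ([[2, -1], [2, -1], [2, -1]], [2, -1]),
        ],
    )
    def test_frame_displacement_max_magnitude_per_axis(self, shifts, expected):
        np.testing.assert_array_equal(
            motion.frame_displacement(np.array(shifts, dtype=float)), expected
        )

    def test_rms_arithmetic(self):
        d = np.array([[3.0, 3.0], [4.0, 4.0]])
        rms = motion.rms_displacement(d, um_per_px=1.0)
        assert rms["x"] == pytest.approx(3.5355, abs=1e-4)
        assert rms["y"] == pytest.approx(3.5355, abs=1e-4)

    def test_rms_zero(self):
        rms = motion.rms_displacement(np.zeros((10, 2)))
        assert rms == {"y": 0.0, "x": 0.0}


class TestCorrectMovie:
    def test_integer_motion_recovered_exactly_and_corrected(self):
        spec = synth.SceneSpec(fov_px=(128, 128), n_cells=15, seed=13)
        masks, _ = synth.make_cells(spec, min_separation_px=10)
        scene = masks.sum(axis=0) * spec.intensity_scale
        T = 8
        rng = np.random.default_rng(1)
        mot = rng.integers(-5, 6, size=(T, 2)).astype(float)
        traces = np.ones((masks.shape[0], T))
        movie, _ = synth.render_movie(masks, traces, mot, None, spec)
        corrected, mf = motion.correct_movie(
            movie, template=scene, grid=motion.PatchGrid((64, 64), (32, 32))
        )
        est = motion.frame_displacement(mf.patch_shifts)
        np.testing.assert_array_equal(est, mot)
        # corrected movie equals the static scene within interpolation loss
        interior = (slice(8, -8), slice(8, -8))
        for frame in corrected:
            rms = np.sqrt(np.mean((frame[interior] - scene[interior]) ** 2))
            assert rms / np.sqrt(np.mean(scene[interior] ** 2)) < 0.02

    def test_idempotence_on_corrected_movie(self):
        spec = synth.SceneSpec(fov_px=(128, 128), n_cells=15, seed=13)
        masks, _ = synth.make_cells(spec, min_separation_px=10)
        scene = masks.sum(axis=0) * spec.intensity_scale
        mot = np.array([[3.0, -2.0], [-4.0, 1.0]])
        movie, _ = synth.render_movie(masks, np.ones((15, 2)), mot, None, spec)
        corrected, _ = motion.correct_movie(
            movie, template=scene, grid=motion.PatchGrid((64, 64), (32, 32))
        )
        _, mf2 = motion.correct_movie(
            corrected, template=scene, grid=motion.PatchGrid((64, 64), (32, 32))
        )
        assert np.abs(mf2.patch_shifts).max() < 0.2

    def test_template_equal_frames_give_zero_field(self, textured_image):
        movie = np.stack([textured_image] * 3)
        _, mf = motion.correct_movie(
            movie, template=textured_image, grid=motion.PatchGrid((64, 64), (32, 32))
        )
        assert np.abs(mf.patch_shifts).max() == 0.0


class TestBetweenTrialOffsets:
    def test_zero_sd_series_near_zero(self):
        spec = synth.SceneSpec(fov_px=(128, 128), seed=6)
        images, _ = synth.make_insertion_series(5, 0.0, spec, seed=6, n_beads=25)
        offs = motion.between_trial_offsets(images, images[0])
        assert np.abs(offs).max() < 0.05

    def test_known_displacements_recovered(self):
        spec = synth.SceneSpec(fov_px=(128, 128), seed=6)
        images, disp = synth.make_insertion_series(8, 0.8, spec, seed=6, n_beads=25)
        ref, _ = synth.make_insertion_series(1, 0.0, spec, seed=6, n_beads=25)
        offs = motion.between_trial_offsets(images, ref[0], upsample_factor=20)
        assert np.abs(offs - disp).max() < 0.1

    def test_recovered_rms_matches_truth_rms(self):
        # the bead-sample registration experiment: n=50 insertions
        spec = synth.SceneSpec(fov_px=(128, 128), seed=8)
        sd_um = 0.8
        images, disp = synth.make_insertion_series(50, sd_um, spec, seed=8, n_beads=25)
        ref, _ = synth.make_insertion_series(1, 0.0, spec, seed=8, n_beads=25)
        offs = motion.between_trial_offsets(images, ref[0], upsample_factor=20)
        rms_est = motion.rms_displacement(offs, spec.um_per_px)
        rms_true = motion.rms_displacement(disp, spec.um_per_px)
        for ax in ("x", "y"):
            assert rms_est[ax] == pytest.approx(rms_true[ax], rel=0.10)

    def test_flat_reference_raises(self):
        with pytest.raises(ValueError):
            motion.between_trial_offsets(np.ones((2, 16, 16)), np.ones((16, 16)))


@pytest.fixture(scope="module")
def stack_and_spec():
    spec = synth.SceneSpec(fov_px=(128, 128), n_cells=15, seed=17)
    masks, _ = synth.make_cells(spec, min_separation_px=10)
    cell_z = synth.cell_axial_offsets(spec, 15)
    stack = synth.make_zstack(masks, spec, z_range_um=(-10, 10), cell_z_um=cell_z)
    return spec, masks, stack, cell_z


class TestEstimateZ:

    def test_frame_equal_to_plane_gives_its_z(self, stack_and_spec):
        _, _, stack, _ = stack_and_spec
        grid = motion.PatchGrid((64, 64), (32, 32))
        for k in (4, 10, 15):
            z = motion.estimate_z(stack.planes[k], stack, grid)
            assert z[0] == pytest.approx(stack.z_um[k], abs=1e-6)

    def test_between_plane_frame_interpolates(self, stack_and_spec):
        _, _, stack, _ = stack_and_spec
        frame = 0.5 * (stack.planes[8] + stack.planes[9])
        z = motion.estimate_z(frame, stack, motion.PatchGrid((64, 64), (32, 32)))
        midpoint = 0.5 * (stack.z_um[8] + stack.z_um[9])
        assert abs(z[0] - midpoint) < 0.25

    def test_monotone_in_true_z(self, stack_and_spec):
        spec, masks, stack, cell_z = stack_and_spec
        true_z = np.linspace(-6, 6, 9)
        movie, _ = synth.render_movie(
            masks, np.ones((masks.shape[0], 9)), None, true_z, spec, cell_z_um=cell_z
        )
        z = motion.estimate_z(movie, stack, motion.PatchGrid((64, 64), (32, 32)))
        assert np.all(np.diff(z) > -0.5)

    def test_all_flat_patches_yield_nan_with_warning(self, stack_and_spec):
        _, _, stack, _ = stack_and_spec
        with pytest.warns(UserWarning):
            z = motion.estimate_z(
                np.zeros((128, 128)), stack, motion.PatchGrid((64, 64), (32, 32))
            )
        assert np.isnan(z[0])

    def test_too_few_planes_raise(self, stack_and_spec):
        _, _, stack, _ = stack_and_spec
        short = synth.ZStack(stack.planes[:2], 1.0, 0.0)
        with pytest.raises(ValueError):
            motion.estimate_z(np.zeros((128, 128)), short)
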