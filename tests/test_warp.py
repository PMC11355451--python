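import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stackalign import (
    CorrectionTrajectory,
    DegenerateFramingError,
    FrameStack,
    FramingSpec,
    ValidationError,
    compute_canvas,
    reframe,
    translate_frame,
)

from conftest import cyclic_shift


class TestTranslateFrame:
    def test_zero_shift_identity(self, textured_frame):
        out = translate_frame(textured_frame, 0.0, 0.0)
        np.testing.assert_allclose(out, textured_frame, atol=1e-12)

    def test_half_pixel_shift_averages_horizontal_neighbors(self):
        frame = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = translate_frame(frame, 0.5, 0.0)
        # out(y, 1) samples input at x = 0.5: mean of the two columns
        assert out[0, 1] == pytest.approx(0.5)
        assert out[1, 1] == pytest.approx(0.5)

    def test_integer_shift_equals_roll_on_overlap(self, textured_frame):
        out = translate_frame(textured_frame, 3, -2, fill=-1.0)
        rolled = cyclic_shift(textured_frame, 3, -2)
        np.testing.assert_allclose(out[:126, 3:], rolled[:126, 3:], atol=1e-9)
        # fill where the source is out of bounds
        assert np.all(out[:, :3] == -1.0)
        assert np.all(out[126:, :] == -1.0)

    def test_non_finite_shift_rejected(self, textured_frame):
        with pytest.raises(ValidationError):
            translate_frame(textured_frame, np.nan, 0.0)

    @given(dx=st.integers(-5, 5), dy=st.integers(-5, 5))
    @settings(max_examples=20)
    def test_integer_shift_then_inverse_is_identity_on_valid_region(self, dx, dy):
        rng = np.random.default_rng(99)
        frame = rng.random((32, 32))
        there = translate_frame(frame, dx, dy, fill=0.0)
        back = translate_frame(there, -dx, -dy, fill=0.0)
        sl_y = slice(max(0, dy, -dy), 32 + min(0, dy, -dy))
        sl_x = slice(max(0, dx, -dx), 32 + min(0, dx, -dx))
        np.testing.assert_allclose(back[sl_y, sl_x], frame[sl_y, sl_x], atol=1e-6)

    def test_fractional_round_trip_within_interpolation_tolerance(self, textured_frame):
        there = translate_frame(textured_frame, 0.4, -0.7, fill=0.0)
        back = translate_frame(there, -0.4, 0.7, fill=0.0)
        region = np.s_[4:-4, 4:-4]
        assert np.abs(back[region] - textured_frame[region]).max() < 0.1


def random_trajectory(rng, T=6, scale=20.0):
    cum = np.vstack([[0.0, 0.0], rng.uniform(-scale, scale, (T - 1, 2))])
    return CorrectionTrajectory(cum)


class TestComputeCanvas:
    def test_zero_trajectory_any_mode(self):
        traj = CorrectionTrajectory(np.zeros((4, 2)))
        for mode in ("maximum", "minimum", "center", "reference"):
            canvas = compute_canvas(traj, (50, 60), FramingSpec(mode=mode))
            assert (canvas.height, canvas.width) == (50, 60)
            np.testing.assert_allclose(canvas.origin_offset, 0.0)

    def test_bounding_box_example(self):
        cum = np.array([[0, 0], [25, 4], [-10, 2]], dtype=float)
        traj = CorrectionTrajectory(cum)
        mx = compute_canvas(traj, (100, 200), FramingSpec(mode="maximum"))
        assert (mx.height, mx.width) == (104, 235)
        mn = compute_canvas(traj, (100, 200), FramingSpec(mode="minimum"))
        assert (mn.height, mn.width) == (96, 165)

    def test_closed_form_for_random_trajectories(self, rng):
        # canvas algebra must match the bounding-box/intersection formulas
        for _ in range(100):
            traj = random_trajectory(rng)
            H, W = 64, 80
            c = -traj.cumulative
            mx = compute_canvas(traj, (H, W), FramingSpec(mode="maximum"))
            assert mx.height == H + int(np.ceil(c[:, 1].max()) - np.floor(c[:, 1].min()))
            assert mx.width == W + int(np.ceil(c[:, 0].max()) - np.floor(c[:, 0].min()))
            mn = compute_canvas(traj, (H, W), FramingSpec(mode="minimum"))
            assert mn.height == H + int(np.floor(c[:, 1].min()) - np.ceil(c[:, 1].max()))
            assert mn.width == W + int(np.floor(c[:, 0].min()) - np.ceil(c[:, 0].max()))
            ct = compute_canvas(traj, (H, W), FramingSpec(mode="center"))
            assert (ct.height, ct.width) == (H, W)
            rf = compute_canvas(traj, (H, W), FramingSpec(mode="reference", reference_index=2))
            assert (rf.height, rf.width) == (H, W)
            np.testing.assert_allclose(
                rf.origin_offset, traj.cumulative[2] - traj.cumulative, atol=1e-12
            )

    def test_empty_intersection_raises(self):
        traj = CorrectionTrajectory(np.array([[0.0, 0.0], [120.0, 0.0]]))
        with pytest.raises(DegenerateFramingError, match="deficit"):
            compute_canvas(traj, (64, 64), FramingSpec(mode="minimum"))


class TestReframe:
    def make_stack(self, rng, T=4):
        from stackalign import band_limited_texture

        frames = np.stack([band_limited_texture((48, 48), 2.0, rng) for _ in range(T)])
        return FrameStack(frames)

    def test_maximum_mode_conserves_content_for_integer_shifts(self, rng):
        stack = self.make_stack(rng)
        traj = CorrectionTrajectory(np.array([[0, 0], [3, -2], [-4, 5], [1, 1]], float))
        out = reframe(stack, traj, FramingSpec(mode="maximum", fill="constant", fill_value=0.0))
        for t in range(stack.n_frames):
            # every input pixel survives: total intensity is conserved
            assert out.frames[t].sum() == pytest.approx(stack.frames[t].sum(), rel=1e-5)

    def test_reference_mode_preserves_dims(self, rng):
        stack = self.make_stack(rng)
        traj = CorrectionTrajectory(rng.uniform(-5, 5, (4, 2)) * [[0], [1], [1], [1]])
        out = reframe(stack, traj, FramingSpec(mode="reference", reference_index=1))
        assert out.frame_shape == stack.frame_shape

    def test_minimum_mode_contains_no_fill_pixels(self, rng):
        stack = self.make_stack(rng)
        traj = CorrectionTrajectory(np.array([[0, 0], [2.5, -3.25], [-1.75, 4.5], [0.5, 0.5]]))
        poison = FramingSpec(mode="minimum", fill="constant", fill_value=-1.0)
        out_raw = reframe(stack, traj, poison)
        # fill value -1 is clipped to 0 on output, so check against a
        # second poison value instead
        poison2 = FramingSpec(mode="minimum", fill="constant", fill_value=1.0)
        out2 = reframe(stack, traj, poison2)
        np.testing.assert_array_equal(out_raw.frames, out2.frames)

    def test_median_brightness_fill_of_constant_frame(self):
        frames = np.full((2, 64, 64), 0.3, dtype=np.float32)
        frames[:, 30:34, 30:34] = 0.3  # keep constant; median is 0.3
        # add minimal variance so the stack is not degenerate for warps
        stack = FrameStack(frames)
        traj = CorrectionTrajectory(np.array([[0.0, 0.0], [10.0, 0.0]]))
        out = reframe(stack, traj, FramingSpec(mode="maximum", fill="median_brightness"))
        # padding regions must be exactly the per-frame median, 0.3
        assert out.frames[0, 0, -1] == pytest.approx(0.3, abs=1e-6)
        assert out.frames[1, 0, 0] == pytest.approx(0.3, abs=1e-6)
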