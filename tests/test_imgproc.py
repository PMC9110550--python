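"""Stabilization, filtering recipe, kymographs and track-width measurement."""

import numpy as np
import pytest

from trackmech import (TimelapseStack, TrackWidthProfile, kymograph,
                       measure_track_width, preprocess, stabilize,
                       width_phase_summary)
from trackmech.imgproc import AFTER, BEFORE, DURING_COLLECTIVE, DURING_SINGLE, NO_TRACK
from trackmech.kinematics import Trajectory
from trackmech.scene import REFLECTION_BASE, Scene, _render_gaussians, generate_stack

from conftest import grip_scene


def make_stack(data, pixel_size=0.32, frame_interval=4.0,
               roles=("reflection", "cytoplasm", "nucleus")):
    return TimelapseStack(np.asarray(data, dtype=np.float32), pixel_size,
                          frame_interval, roles[: data.shape[1]])


class TestStabilize:
    @pytest.mark.parametrize("drift", [(3.0, -2.0), (0.0, 0.0), (0.5, 0.5)])
    def test_injected_drift_recovered(self, drift):
        scene = Scene(image_shape=(256, 256), n_frames=4, wall_force_peak=0.0,
                      drift_per_frame=drift, seed=2)
        stack, _ = generate_stack(scene)
        result = stabilize(stack)
        expected = -np.outer(np.arange(4), drift)  # correction negates the drift
        np.testing.assert_allclose(result.shifts, expected, atol=0.1)

    def test_residual_shift_after_stabilization_below_half_pixel(self):
        scene = Scene(image_shape=(256, 256), n_frames=4, wall_force_peak=0.0,
                      drift_per_frame=(2.3, -1.1), seed=2)
        stack, _ = generate_stack(scene)
        stabilized = stabilize(stack).stack
        residual = stabilize(stabilized).shifts
        assert np.abs(residual).max() < 0.5

    def test_flat_frame_flagged_with_zero_shift(self):
        data = np.zeros((3, 1, 32, 32), dtype=np.float32)
        data[0, 0, 10:20, 10:20] = 1.0
        data[2, 0, 10:20, 10:20] = 1.0
        stack = make_stack(data, roles=("reflection",))
        result = stabilize(stack)
        assert 1 in result.flat_frames
        np.testing.assert_array_equal(result.shifts[1], [0, 0])


class TestPreprocess:
    def test_constant_stack_unchanged_and_idempotent(self):
        stack = make_stack(np.full((4, 3, 24, 24), 0.7))
        out = preprocess(stack)
        np.testing.assert_allclose(out.data, stack.data, atol=1e-6)
        out2 = preprocess(out)
        np.testing.assert_allclose(out2.data, out.data, atol=1e-6)
        assert out.data.shape == stack.data.shape

    def test_fluorescence_impulse_removed_by_median(self):
        data = np.zeros((2, 3, 24, 24), dtype=np.float32)
        data[0, 1, 12, 12] = 10.0  # single-pixel impulse in cytoplasm channel
        out = preprocess(make_stack(data))
        assert out.data[0, 1, 12, 12] == 0.0

    def test_reflection_flicker_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.8, size=(9, 1, 12, 12)).astype(np.float32)
        flicker = base + 0.3 * (-1.0) ** np.arange(9)[:, None, None, None]
        stack = make_stack(flicker.astype(np.float32), roles=("reflection",))
        out = preprocess(stack).data[:, 0]

        # brute-force truncated spatiotemporal mean
        vol = flicker[:, 0]
        expected = np.zeros_like(vol)
        for t in range(9):
            for y in range(12):
                for x in range(12):
                    ts = slice(max(t - 2, 0), min(t + 3, 9))
                    ys = slice(max(y - 1, 0), min(y + 2, 12))
                    xs = slice(max(x - 1, 0), min(x + 2, 12))
                    expected[t, y, x] = vol[ts, ys, xs].mean()
        np.testing.assert_allclose(out, expected, atol=1e-5)


class TestKymograph:
    def test_static_scene_rows_constant_in_time(self):
        scene = Scene(image_shape=(128, 128), n_frames=5, wall_force_peak=0.0,
                      noise_sd=0.0, seed=3)
        stack, _ = generate_stack(scene)
        line = np.array([[5.0, 5.0], [35.0, 35.0]])
        k = kymograph(stack, line, "reflection")
        assert k.data.shape[1] == 5
        assert np.ptp(k.data, axis=1).max() < 1e-5

    def test_moving_edge_slope_matches_velocity(self):
        # an intensity edge advancing at v µm/min along x
        v, dt, ps = 0.5, 4.0, 0.32
        ny = nx = 96
        T = 10
        data = np.zeros((T, 1, ny, nx), dtype=np.float32)
        xs = np.arange(nx) * ps
        for t in range(T):
            edge = 5.0 + v * dt * t
            data[t, 0] = (xs[None, :] < edge).astype(np.float32)
        stack = make_stack(data, roles=("cytoplasm",))
        line = np.array([[0.0, 15.0], [28.0, 15.0]])
        k = kymograph(stack, line, "cytoplasm")
        pos = k.positions_um()
        loci = np.array([pos[np.argmax(k.data[:, t] < 0.5)] for t in range(T)])
        slope = np.polyfit(np.arange(T) * dt, loci, 1)[0]
        assert slope == pytest.approx(v, rel=0.10)

    def test_single_point_line_gives_1xT(self, static_scene):
        _, stack, _ = static_scene
        k = kymograph(stack, np.array([[10.0, 10.0]]), "reflection")
        assert k.data.shape == (1, stack.n_frames)

    def test_out_of_bounds_polyline_rejected(self, static_scene):
        _, stack, _ = static_scene
        with pytest.raises(ValueError, match="bounds"):
            kymograph(stack, np.array([[0.0, 0.0], [1e4, 0.0]]), "reflection")


class TestTrackWidth:
    def test_rendered_gap_measured_within_half_micron(self):
        scene = Scene(image_shape=(256, 256), track_width0=10.0,
                      wall_force_peak=0.0, n_frames=2, seed=4)
        stack, _ = generate_stack(scene)
        m = measure_track_width(stack, 40.0, 0)
        assert m.found
        assert m.width_um == pytest.approx(10.0, abs=0.5)

    def test_narrow_track_widened_fourfold_by_pushing(self):
        # 2.6 µm track widened to 4x by a pushing cell
        target = 4 * 2.6
        d = (target - 2.6) / 2.0
        force = 340.0 * (d / 40.0) * 400.0 * 1e-3
        scene = grip_scene(force, track_width0=2.6, deformation_sign="push",
                           image_shape=(384, 320), seed=4)
        stack, _ = generate_stack(scene)
        before = measure_track_width(stack, scene.pause_at_x, 0)
        during = measure_track_width(stack, scene.pause_at_x, 28)
        assert during.width_um / before.width_um == pytest.approx(4.0, rel=0.10)

    def test_uniform_collagen_reports_no_track(self):
        rng = np.random.default_rng(1)
        img = np.full((256, 256), REFLECTION_BASE)
        _render_gaussians(img, rng.uniform(0, 80, size=(300, 2)), 0.6, 0.7, 0.32)
        img = img + rng.normal(0, 0.05, img.shape)
        stack = make_stack(img[None, None], roles=("reflection",))
        m = measure_track_width(stack, 40.0, 0)
        assert m.status == NO_TRACK
        assert np.isnan(m.width_um)

    def test_invariant_to_global_intensity_scaling(self):
        scene = Scene(image_shape=(256, 256), track_width0=10.0,
                      wall_force_peak=0.0, n_frames=2, seed=4)
        stack, _ = generate_stack(scene)
        m1 = measure_track_width(stack, 40.0, 0)
        m2 = measure_track_width(stack.with_data(stack.data * 3.7), 40.0, 0)
        assert m1.width_um == pytest.approx(m2.width_um, abs=1e-6)

    def test_position_outside_image_rejected(self, static_scene):
        _, stack, _ = static_scene
        with pytest.raises(ValueError):
            measure_track_width(stack, 1e4, 0)


def _cell_trajs(x_lead, x_rear, y=64.0, dt=4.0):
    n = len(x_lead)
    lead = Trajectory("c", "leading", np.column_stack([x_lead, [y] * n]), dt)
    rear = Trajectory("c", "rear", np.column_stack([x_rear, [y] * n]), dt)
    return {"leading": lead, "rear": rear}


class TestWidthPhases:
    def test_cell_never_reaching_position_keeps_all_before(self, static_scene):
        scene, stack, _ = static_scene
        profile = TrackWidthProfile.measure(stack, [40.0])
        trajs = _cell_trajs([5.0] * 4, [1.0] * 4)
        table, summary = width_phase_summary(profile, trajs)
        assert set(table.phase) == {BEFORE}

    def test_pull_narrowing_22_to_11_gives_half_ratio(self):
        # forces chosen from the closed form so the wall moves in by 5.5 µm
        force = 340.0 * (5.5 / 40.0) * 400.0 * 1e-3
        scene = Scene(image_shape=(400, 320), track_width0=22.0,
                      wall_force_peak=force, n_frames=30, ramp_frames=8,
                      cell_length=30.0, cell_speed=1.0, seed=4)
        stack, truth = generate_stack(scene)
        profile = TrackWidthProfile.measure(stack, [50.0])
        trajs = {
            "leading": Trajectory("c", "leading",
                                  np.column_stack([scene.cell_x(np.arange(30)) + 15,
                                                   [scene.axis_y] * 30]), 4.0),
            "rear": Trajectory("c", "rear",
                               np.column_stack([scene.cell_x(np.arange(30)) - 15,
                                                [scene.axis_y] * 30]), 4.0),
        }
        table, summary = width_phase_summary(profile, trajs)
        assert {BEFORE, DURING_SINGLE, AFTER} <= set(table.phase)
        before = table[table.phase == BEFORE].width_um.mean()
        during_min = table[table.phase == DURING_SINGLE].width_um.min()
        assert during_min / before == pytest.approx(0.50, abs=0.05)

    def test_no_plasticity_restores_width_after_passage(self):
        force = 340.0 * (5.5 / 40.0) * 400.0 * 1e-3
        scene = Scene(image_shape=(400, 320), track_width0=22.0,
                      wall_force_peak=force, n_frames=30, ramp_frames=8,
                      plasticity=0.0, cell_length=30.0, cell_speed=1.0, seed=4)
        stack, _ = generate_stack(scene)
        profile = TrackWidthProfile.measure(stack, [50.0])
        xs = scene.cell_x(np.arange(30))
        trajs = _cell_trajs(xs + 15, xs - 15, y=scene.axis_y)
        table, _ = width_phase_summary(profile, trajs)
        before = table[table.phase == BEFORE].width_um.mean()
        after = table[table.phase == AFTER].width_um
        assert len(after) > 0
        assert after.iloc[-1] == pytest.approx(before, abs=0.5)

    def test_two_overlapping_cells_labelled_collective(self, static_scene):
        _, stack, _ = static_scene
        profile = TrackWidthProfile.measure(stack, [40.0])
        cell1 = _cell_trajs([50.0] * 4, [30.0] * 4)
        cell2 = _cell_trajs([45.0] * 4, [25.0] * 4)
        table, _ = width_phase_summary(profile, [cell1, cell2])
        assert set(table.phase) == {DURING_COLLECTIVE}
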