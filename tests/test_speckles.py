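"""Speckle tracking, strain, force conversion and the consensus estimator."""

import numpy as np
import pytest

from trackmech import (ElasticModel, SpeckleTrajectory, TrackGeometry,
                       compute_force, compute_strain, displacement_field,
                       estimate_traction_force, preprocess, stabilize,
                       track_speckles)
from trackmech.scene import generate_stack

from conftest import grip_scene, truth_path


def synthetic_traj(positions, sid="s", dt=4.0, lost_from=None):
    positions = np.asarray(positions, dtype=float)
    return SpeckleTrajectory(speckle_id=sid, positions=positions,
                             quality=np.ones(len(positions)),
                             frame_interval=dt, lost_from=lost_from)


def wall_side_seeds(truth, scene, r_range=(4.0, 18.0), dx_max=6.0, side=+1):
    """Ground-truth speckles near the contact on one side of the track."""
    spk = truth.speckle_positions(0)
    axis, half = scene.axis_y, scene.track_width0 / 2.0
    r = side * (spk.y_um - axis) - half
    dx = (spk.x_um - scene.pause_at_x).abs()
    sel = spk[(r >= r_range[0]) & (r <= r_range[1]) & (dx <= dx_max)]
    return sel.reset_index(drop=True)


class TestTrackSpeckles:
    def test_static_stack_displacements_below_fifth_of_pixel(self, static_scene):
        scene, stack, truth = static_scene
        pp = preprocess(stack)
        seeds = truth.speckle_positions(0)[["x_um", "y_um"]].to_numpy()[:10]
        # keep seeds away from borders
        seeds = seeds[(seeds[:, 0] > 5) & (seeds[:, 0] < 75)
                      & (seeds[:, 1] > 5) & (seeds[:, 1] < 75)][:6]
        trajs = track_speckles(pp, seeds)
        for tr, seed in zip(trajs, seeds):
            disp = np.hypot(*(tr.positions - seed).T)
            assert np.nanmax(disp) < 0.2 * stack.pixel_size

    def test_rigid_translation_recovered(self, static_scene):
        scene, stack, truth = static_scene
        refl = stack.channel("reflection")[0]
        data = np.stack([stack.data[0],
                         np.roll(stack.data[0], (2, 1), axis=(-2, -1))])
        rigid = stack.with_data(data)
        seeds = truth.speckle_positions(0)[["x_um", "y_um"]].to_numpy()
        seeds = seeds[(seeds[:, 0] > 8) & (seeds[:, 0] < 72)
                      & (seeds[:, 1] > 8) & (seeds[:, 1] < 72)][:6]
        trajs = track_speckles(rigid, seeds)
        ps = stack.pixel_size
        for tr in trajs:
            step = tr.positions[1] - tr.positions[0]
            assert step[0] == pytest.approx(1 * ps, abs=0.2 * ps)  # x = columns
            assert step[1] == pytest.approx(2 * ps, abs=0.2 * ps)  # y = rows

    def test_deformation_scenario_rms_below_half_pixel(self):
        scene = grip_scene(10.0, seed=7)
        stack, truth = generate_stack(scene)
        pp = preprocess(stabilize(stack).stack)
        errors = []
        for side in (+1, -1):
            sel = wall_side_seeds(truth, scene, side=side).head(4)
            trajs = track_speckles(pp, sel[["x_um", "y_um"]].to_numpy(),
                                   template_px=13, search_px=6)
            for tr, oid in zip(trajs, sel.object_id):
                path = truth_path(truth, oid)
                n = tr.n_valid
                errors.append(np.hypot(*(tr.positions[:n] - path[:n]).T))
        rms = np.sqrt(np.mean(np.concatenate(errors) ** 2))
        assert rms < 0.5 * scene.pixel_size

    def test_even_template_rejected(self, static_scene):
        _, stack, _ = static_scene
        with pytest.raises(ValueError, match="odd"):
            track_speckles(stack, [[40.0, 40.0]], template_px=8)

    def test_border_seed_rejected(self, static_scene):
        _, stack, _ = static_scene
        with pytest.raises(ValueError, match="border"):
            track_speckles(stack, [[0.5, 40.0]])


class TestStrain:
    def test_separation_increase_arithmetic(self):
        a = synthetic_traj([[0, 0], [0, 0]])
        b = synthetic_traj([[20, 0], [22, 0]])
        s = compute_strain(a, b)
        assert s.strain[0] == 0.0
        assert s.strain[1] == pytest.approx(0.10)

    def test_no_motion_zero_strain(self):
        a = synthetic_traj([[0, 0]] * 5)
        b = synthetic_traj([[10, 0]] * 5)
        assert np.all(compute_strain(a, b).strain == 0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        a = synthetic_traj(rng.uniform(0, 50, (6, 2)))
        b = synthetic_traj(rng.uniform(60, 100, (6, 2)))
        np.testing.assert_allclose(compute_strain(a, b).strain,
                                   compute_strain(b, a).strain)

    def test_small_baseline_rejected(self):
        a = synthetic_traj([[0, 0], [0, 0]])
        b = synthetic_traj([[1.0, 0], [1.5, 0]])
        with pytest.raises(ValueError, match="separation"):
            compute_strain(a, b)

    def test_lost_trajectory_truncates_series(self):
        a = synthetic_traj([[0, 0]] * 6, lost_from=4)
        b = synthetic_traj([[10, 0]] * 6)
        assert len(compute_strain(a, b).strain) == 4

    def test_measured_pair_strain_matches_truth_path_strain(self):
        # tracked strain vs strain computed on the exact generator paths
        scene = grip_scene(20.0, seed=7)
        stack, truth = generate_stack(scene)
        pp = preprocess(stabilize(stack).stack)
        near = wall_side_seeds(truth, scene, r_range=(6.0, 14.0), dx_max=2.0).iloc[0]
        far = wall_side_seeds(truth, scene, r_range=(34.0, 42.0), dx_max=6.0).iloc[0]
        seeds = np.array([[near.x_um, near.y_um], [far.x_um, far.y_um]])
        ta, tb = track_speckles(pp, seeds, template_px=13, search_px=6)
        measured = compute_strain(ta, tb)
        oracle = compute_strain(synthetic_traj(truth_path(truth, near.object_id)),
                                synthetic_traj(truth_path(truth, far.object_id)))
        # compare over the grip phase (the analysed deformation window)
        n = min(len(measured.strain),
                int(np.ceil(scene.grip_start_frame())) + scene.pause_frames + 1)
        peak = np.abs(oracle.strain[:n]).max()
        np.testing.assert_allclose(measured.strain[:n], oracle.strain[:n],
                                   atol=0.05 * peak + 0.01)


class TestForce:
    def test_linear_relation_hand_arithmetic(self):
        s = synthetic_traj([[0, 0], [0, 0]])
        series = compute_strain(s, synthetic_traj([[20, 0], [25.88, 0]]))
        force = compute_force(series, ElasticModel(340.0, 400.0))
        # s = 0.294 -> F = 340 * 0.294 * 400 * 1e-3 = 39.98 nN
        assert force.force_nN[1] == pytest.approx(340 * 0.294 * 400 * 1e-3, abs=0.05)
        assert force.force_nN[0] == 0.0

    def test_force_linearity_in_strain_E_and_A(self):
        base = compute_force(
            compute_strain(synthetic_traj([[0, 0], [0, 0]]),
                           synthetic_traj([[20, 0], [22, 0]])),
            ElasticModel(340.0, 400.0))
        double_strain = compute_force(
            compute_strain(synthetic_traj([[0, 0], [0, 0]]),
                           synthetic_traj([[20, 0], [24, 0]])),
            ElasticModel(340.0, 400.0))
        double_E = compute_force(base.strain, ElasticModel(680.0, 400.0))
        double_A = compute_force(base.strain, ElasticModel(340.0, 800.0))
        assert double_strain.force_nN[1] == pytest.approx(2 * base.force_nN[1])
        assert double_E.force_nN[1] == pytest.approx(2 * base.force_nN[1])
        assert double_A.force_nN[1] == pytest.approx(2 * base.force_nN[1])

    def test_contact_area_of_20um_square(self):
        side = 20.0
        model = ElasticModel(contact_area=side * side)
        assert model.contact_area == 400.0

    def test_direction_flag_tracks_strain_sign(self):
        a = synthetic_traj([[0, 0], [0, 0], [0, 0]])
        b = synthetic_traj([[20, 0], [22, 0], [18, 0]])
        f = compute_force(compute_strain(a, b))
        assert f.direction[1] == 1 and f.direction[2] == -1
        assert (f.force_nN >= 0).all()


class TestDisplacementField:
    def test_static_gives_zero_vectors(self):
        trajs = [synthetic_traj([[10, 10]] * 4, sid="a"),
                 synthetic_traj([[20, 20]] * 4, sid="b")]
        field = displacement_field(trajs, 3)
        assert field.max_magnitude_um == 0.0

    def test_single_trajectory_field_of_size_one(self):
        field = displacement_field([synthetic_traj([[10, 10], [11, 10]])], 1)
        assert len(field.table) == 1
        assert field.max_magnitude_um == pytest.approx(1.0)

    def test_magnitude_decays_away_from_track_edge(self, grip20, grip20_processed):
        scene, _, truth = grip20
        sel = wall_side_seeds(truth, scene, r_range=(2.0, 39.0), dx_max=8.0)
        assert len(sel) >= 20
        trajs = track_speckles(grip20_processed,
                               sel[["x_um", "y_um"]].to_numpy(),
                               template_px=13, search_px=6)
        t_peak = int(np.ceil(scene.grip_start_frame())) + scene.ramp_frames + 3
        field = displacement_field(trajs, t_peak)
        wall_y = scene.axis_y + scene.track_width0 / 2.0
        rho, p = field.monotone_decay(wall_y)
        assert rho < 0
        assert p < 0.05


class TestConsensusTraction:
    @pytest.mark.parametrize("force", [10.0, 20.0, 40.0])
    def test_round_trip_recovers_peak_within_15_percent(self, force):
        scene = grip_scene(force, seed=7)
        stack, truth = generate_stack(scene)
        pp = preprocess(stabilize(stack).stack)
        geometry = TrackGeometry(axis_y_um=scene.axis_y,
                                 half_width_um=scene.track_width0 / 2.0,
                                 contact_x_um=scene.pause_at_x,
                                 clamp_distance_um=scene.clamp_distance,
                                 contact_length_um=scene.contact_length)
        end = int(np.ceil(scene.grip_start_frame())) + scene.pause_frames
        est = estimate_traction_force(
            pp, truth.speckle_positions(0)[["x_um", "y_um"]].to_numpy(),
            geometry, end_frame=end)
        assert est.peak_nN == pytest.approx(force, rel=0.15)

    def test_pipeline_deterministic(self):
        scene = grip_scene(10.0, seed=3, image_shape=(320, 256), pause_at_x=40.0)
        results = []
        for _ in range(2):
            stack, truth = generate_stack(scene)
            pp = preprocess(stabilize(stack).stack)
            geometry = TrackGeometry(scene.axis_y, scene.track_width0 / 2.0,
                                     scene.pause_at_x, scene.clamp_distance,
                                     scene.contact_length)
            est = estimate_traction_force(
                pp, truth.speckle_positions(0)[["x_um", "y_um"]].to_numpy(),
                geometry)
            results.append(est.force_nN)
        np.testing.assert_array_equal(results[0], results[1])
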