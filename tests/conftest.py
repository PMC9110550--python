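"""Shared fixtures: synthetic scenes reused across test modules."""

import numpy as np
import pytest

from trackmech import preprocess, stabilize
from trackmech.scene import Scene, generate_stack


def grip_scene(force_nN: float, seed: int = 7, **overrides) -> Scene:
    """Wide-track pull scenario: the cell crawls in, stops, grips and pulls.

    Geometry leaves a full clamp distance of collagen on both sides of the
    30 µm track; the force ramps over 40 min at the stationary contact.
    """
    params = dict(
        image_shape=(400, 320), track_width0=30.0, wall_force_peak=force_nN,
        clamp_distance=40.0, n_frames=36, ramp_frames=10, cell_length=30.0,
        cell_speed=0.5, pause_at_x=50.0, pause_frames=16, seed=seed,
    )
    params.update(overrides)
    return Scene(**params)


@pytest.fixture(scope="session")
def grip20():
    """Rendered 20 nN grip scenario with its ground truth."""
    scene = grip_scene(20.0)
    stack, truth = generate_stack(scene)
    return scene, stack, truth


@pytest.fixture(scope="session")
def grip20_processed(grip20):
    """Stabilized + preprocessed version of the 20 nN grip stack."""
    _, stack, _ = grip20
    return preprocess(stabilize(stack).stack)


@pytest.fixture(scope="session")
def static_scene():
    """Small static scene (no force, no drift): speckled track at rest."""
    scene = Scene(image_shape=(256, 256), n_frames=4, wall_force_peak=0.0, seed=2)
    stack, truth = generate_stack(scene)
    return scene, stack, truth


def truth_path(truth, object_id: str) -> np.ndarray:
    """Ground-truth (n, 2) µm path of one object."""
    t = truth.trajectories
    sel = t[t.object_id == object_id].sort_values("frame")
    return sel[["x_um", "y_um"]].to_numpy(dtype=float)
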