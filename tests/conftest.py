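import numpy as np
import pandas as pd
import pytest

from foragekit import encounter_detection, synthetic_world


@pytest.fixture(scope="session")
def grid_arena():
    return synthetic_world.generate_world("isometric_grid", 10.0, 1)


@pytest.fixture(scope="session")
def default_params():
    return synthetic_world.BehaviorParams()


@pytest.fixture(scope="session")
def small_population(grid_arena, default_params):
    """Five worms, 30 min each — shared by detection/classification tests."""
    trajs, truth = synthetic_world.simulate_population(
        grid_arena, default_params, 5, 1800.0, 42)
    return trajs, truth


@pytest.fixture(scope="session")
def detected_encounters(grid_arena, default_params, small_population):
    trajs, _ = small_population
    frames = []
    for traj in trajs:
        recs = encounter_detection.detect_encounters(traj, grid_arena)
        frames.append(encounter_detection.encounters_to_frame(
            recs, default_params.fps))
    return pd.concat(frames, ignore_index=True)


def make_line_trajectory(speed_mm_s, fps, n_frames, start=(-3.0, 0.0),
                         direction=(1.0, 0.0), worm_id=0):
    """Constant-velocity straight-line track (analytic oracle helper)."""
    t = np.arange(n_frames) / fps
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    x = start[0] + speed_mm_s * t * d[0]
    y = start[1] + speed_mm_s * t * d[1]
    return synthetic_world.TrajectoryRecord(worm_id, t, x, y, fps)


@pytest.fixture
def line_trajectory():
    return make_line_trajectory
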