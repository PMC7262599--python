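"""Shared fixtures: small synthetic scenes and movies.

Module-scoped fixtures keep the suite fast; everything is generated at
test time from fixed seeds, no binary fixtures on disk.
"""

import numpy as np
import pytest

from centrodyn.config import PipelineConfig
from centrodyn.synth import (
    SceneConfig,
    TrajectoryProgram,
    make_scene,
    render_movie,
    simulate_pair,
)


@pytest.fixture(scope="session")
def scene():
    """Default U2OS-like scene (256 px, 0.2 μm/px, 5-min frames)."""
    return make_scene(SceneConfig(n_frames=30))


@pytest.fixture(scope="session")
def small_scene():
    """Compact scene for cheap rendering tests."""
    return make_scene(
        SceneConfig(
            shape_px=(128, 128),
            nucleus_semiaxes_um=(5.0, 3.5),
            cell_semiaxes_um=(11.0, 9.0),
            n_frames=8,
        )
    )


@pytest.fixture(scope="session")
def separation_truth(scene):
    return simulate_pair(
        TrajectoryProgram(mode="separation", speeds_um_min=(0.3, 0.3)),
        scene, seed=11,
    )


@pytest.fixture(scope="session")
def separation_stack(scene, separation_truth):
    return render_movie(scene, separation_truth, seed=11)


@pytest.fixture(scope="session")
def congression_truth(scene):
    return simulate_pair(
        TrajectoryProgram(mode="congression", speeds_um_min=(0.3, 0.1)),
        scene, seed=12,
    )


@pytest.fixture(scope="session")
def congression_stack(scene, congression_truth):
    return render_movie(scene, congression_truth, seed=12)


@pytest.fixture(scope="session")
def stationary_stack(small_scene):
    truth = simulate_pair(
        TrajectoryProgram(mode="stationary", target_distance_um=8.0),
        small_scene, seed=13,
    )
    return render_movie(small_scene, truth, seed=13), truth


@pytest.fixture()
def config():
    return PipelineConfig()


def truth_positions_px(truth, scene, frame):
    """Helper: true (x, y) px positions of both centrosomes at a frame."""
    px = scene.config.pixel_size_um
    sub = truth.table[truth.table.frame == frame].sort_values("centrosome_id")
    return sub[["x_um", "y_um"]].to_numpy() / px
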