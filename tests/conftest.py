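import numpy as np
import pytest

from swarmtrack.synthgen import (
    GroundTruthTrajectorySet,
    MotilityModelParams,
    RenderParams,
    render_frames,
    simulate_fbm_trajectories,
)


def make_grid_scene(
    n_cols: int = 6,
    n_rows: int = 5,
    n_frames: int = 20,
    sigma_step: float = 0.15,
    seed: int = 11,
) -> GroundTruthTrajectorySet:
    """Well-separated slow cells on a grid inside a 51.2 µm field."""
    n_cells = n_cols * n_rows
    params = MotilityModelParams(
        model="fbm",
        hurst=0.5,
        sigma_step=sigma_step,
        n_cells=n_cells,
        n_frames=n_frames,
        frame_interval=0.5,
        seed=seed,
    )
    tset = simulate_fbm_trajectories(params)
    gx, gy = np.meshgrid(
        4.8 + 7.0 * np.arange(n_cols), 5.0 + 8.6 * np.arange(n_rows)
    )
    offsets = np.column_stack([gx.ravel(), gy.ravel()])
    tset.positions = tset.positions + offsets[:, None, :]
    return tset


@pytest.fixture(scope="session")
def grid_scene():
    """(ground truth, rendered stack) for a 30-cell high-SNR time lapse."""
    tset = make_grid_scene()
    stack = render_frames(tset, RenderParams(), seed=4)
    return tset, stack
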