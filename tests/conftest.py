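import numpy as np
import pytest

import smfishq as sq


@pytest.fixture(scope="session")
def small_params():
    """Compact field for unit tests: full acquisition geometry, fewer cells."""
    return sq.ScenarioParams(seed=11, n_cells=8)


@pytest.fixture(scope="session")
def cell_scene(small_params):
    return sq.sample_scene(small_params)


@pytest.fixture(scope="session")
def fish_stack(cell_scene):
    return sq.render_stack(cell_scene, "FISH")


@pytest.fixture(scope="session")
def if_stack(cell_scene):
    return sq.render_stack(cell_scene, "IF")


@pytest.fixture(scope="session")
def position_result(cell_scene, fish_stack, if_stack):
    """Full single-position analysis shared across tests."""
    outlines = sq.scene_outlines(cell_scene)
    return sq.analyze_position(fish_stack, outlines, sq.DetectionSettings(), if_stack=if_stack)


@pytest.fixture(scope="session")
def sparse_scene():
    params = sq.ScenarioParams(seed=3, field_shape=(41, 256, 256))
    return sq.make_sparse_scene(40, params)


@pytest.fixture(scope="session")
def sparse_fish(sparse_scene):
    return sq.render_stack(sparse_scene, "FISH")


@pytest.fixture(scope="session")
def sparse_table(sparse_fish):
    from smfishq.pipeline import refine_q_bounds
    from smfishq.detect import filter_spots

    table = sq.detect_spots(sparse_fish, sq.DetectionSettings())
    return filter_spots(table, refine_q_bounds(table))


def single_spot_stack(
    Q=6912.0, sigma_xy=130.0, sigma_z=350.0, center=None, shape=(21, 25, 25),
    offset=100.0, noise_seed=None, bg_fluor=20.0, gain=2.0, read_sd=2.0,
):
    """Render one voxel-integrated Gaussian spot, optionally with camera noise."""
    from smfishq.simulate import _add_gaussian

    voxel = (200.0, 64.5, 64.5)
    nz, ny, nx = shape
    if center is None:
        center = ((nx / 2) * 64.5, (ny / 2) * 64.5, (nz / 2) * 200.0)
    E = np.zeros(shape)
    _add_gaussian(E, voxel, center[0], center[1], center[2], Q, sigma_xy, sigma_z)
    if noise_seed is None:
        data = E + offset
    else:
        rng = np.random.default_rng(noise_seed)
        data = offset + gain * rng.poisson((E + bg_fluor) / gain) + rng.normal(0, read_sd, E.shape)
        data = np.clip(data, 0, None)
    return sq.ImageStack(data, voxel_size=voxel), center
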