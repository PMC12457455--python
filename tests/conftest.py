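import numpy as np
import pytest

from foresttraj import CellSpec, TrajectorySpec, generate_lc_series


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def loss_cell():
    """Noise-free cell: gradual persistent loss of 30 pixels over 10 years."""
    spec = CellSpec(
        initial_transition_amount=80,
        trajectory=TrajectorySpec(
            direction="loss", change_pixels=30, start_step=2,
            duration_years=10, shape="gradual",
        ),
        seed=7,
        cell_id="loss_cell",
    )
    return spec, generate_lc_series(spec)


def random_masks(rng, n, rows, cols):
    """n random binary grids with uniformly random fill levels."""
    p = rng.uniform(0.02, 0.98, size=n)
    return rng.random((n, rows, cols)) < p[:, None, None]
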