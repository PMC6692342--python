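import numpy as np
import pytest

from mutshift import SyntheticConfig, generate_pair
from mutshift.trajectory_io import Trajectory, superpose_to_first_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_pair():
    """Default desk-scale synthetic pair with ground truth (seed 0)."""
    return generate_pair(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def desk_aligned(desk_pair):
    wt, mut, gt = desk_pair
    return superpose_to_first_frame(wt), superpose_to_first_frame(mut), gt


def make_trajectory(coords, times=None, tag="", aligned=False, labels=None):
    coords = np.asarray(coords, dtype=float)
    m, n, _ = coords.shape
    if times is None:
        times = np.arange(m) * 10.0
    if labels is None:
        labels = [(k + 1, "GLY") for k in range(n)]
    return Trajectory(coords, labels, times, condition_tag=tag, aligned=aligned)


@pytest.fixture
def static_three_residues():
    """Three static residues at mutual distances 5, 8 and ~12.2 Å."""
    frame = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [0.0, 8.0, 0.0]])
    return make_trajectory(np.repeat(frame[None], 4, axis=0), aligned=True)
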