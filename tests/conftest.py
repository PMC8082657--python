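import numpy as np
import pytest

from plaqueangio.config import SimulationConfig
from plaqueangio.geometry import make_synthetic_fixture, segment_domain


@pytest.fixture(scope="session")
def small_fixture():
    """Mirror-symmetric crescent segmentation input on a 100x100 grid."""
    return make_synthetic_fixture(seed=1, stenosis_fraction=0.8, nx=100, ny=100)


@pytest.fixture(scope="session")
def small_domain(small_fixture):
    return segment_domain(small_fixture)


@pytest.fixture(scope="session")
def full_domain():
    """The baseline 200x200 geometry (80% stenosis)."""
    return segment_domain(make_synthetic_fixture(seed=1, stenosis_fraction=0.8))


@pytest.fixture(scope="session")
def baseline_coeffs():
    return SimulationConfig().step_coefficients()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_random_tree_network(rng, n_nodes=30, ny=64, nx=64):
    """Random grid-embedded vessel tree rooted at one seed (test helper)."""
    from plaqueangio.angiogenesis import OFFSETS, VesselNetwork

    net = VesselNetwork(ny=ny, nx=nx, h_cm=0.4 / nx)
    start = (nx // 2, ny // 2)
    net.roots = np.array([start])
    net.A[start[1], start[0]] = True
    nodes = [start]
    guard = 0
    while len(nodes) < n_nodes and guard < 50 * n_nodes:
        guard += 1
        x, y = nodes[rng.integers(len(nodes))]
        k = int(rng.integers(1, 9))
        dx, dy = OFFSETS[k]
        tx, ty = x + dx, y + dy
        if not (0 < tx < nx - 1 and 0 < ty < ny - 1):
            continue
        if net.A[ty, tx]:
            continue
        net.add_segment((x, y), (tx, ty))
        nodes.append((tx, ty))
    return net
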