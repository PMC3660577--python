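import numpy as np
import pytest

from kicloop.fixtures import FixtureSpec, generate_fixture
from kicloop.geometry import SegmentDefinition, build_coordinates, new_pose
from kicloop.priors import default_tables


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def loop_pose():
    """A 16-residue closed chain with varied torsions for closure tests."""
    rng = np.random.default_rng(3)
    n = 16
    p = new_pose("ASLVTNDKGASLVTND")
    p.phi[:] = rng.uniform(-150.0, -50.0, n)
    p.psi[:] = rng.uniform(-60.0, 150.0, n)
    p.omega[:] = 180.0
    p.theta[:] = rng.uniform(109.62, 112.1, n)
    return build_coordinates(p)


@pytest.fixture(scope="session")
def loop_segment():
    return SegmentDefinition(3, 14)


@pytest.fixture(scope="session")
def small_fixture(tables):
    """One bundled-style synthetic fixture (native, start, segment)."""
    return generate_fixture(FixtureSpec(seed=11), tables)


def random_move(pose, segment, rng, omega=180.0):
    """A random closure proposal on a random sub-segment."""
    from kicloop.closure import choose_subsegment, sample_bond_angles

    mv = choose_subsegment(segment, rng)
    L = mv.length
    mv.phi[:] = rng.uniform(-180.0, 180.0, L)
    mv.psi[:] = rng.uniform(-180.0, 180.0, L)
    mv.omega[:] = omega
    return sample_bond_angles(mv, "varied", rng)
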