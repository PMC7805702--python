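import numpy as np
import pytest

from nichesim import PreyParams, WorldConfig, build_world


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_world():
    return build_world(WorldConfig())


@pytest.fixture
def settled_world():
    """Default world stepped until both agents rest on the floor."""
    w = build_world(WorldConfig())
    for _ in range(60):
        w.step()
    return w


@pytest.fixture
def prey_params():
    return PreyParams()


def world_state_arrays(world):
    """Copy of everything that defines the dynamic state of a world."""
    return (world.pos.copy(), world.angle.copy(), world.vel.copy(),
            world.angvel.copy(), world.active.copy(), world.kind.copy(),
            world.half.copy())
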