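import numpy as np
import pytest

from ringpe import forcefield as ff


@pytest.fixture
def rng():
    return np.random.default_rng(20240729)


def random_system(seed: int, n: int = 12, n_mono: int = 6, box: float = 12.0,
                  min_sep: float = 0.5) -> ff.ParticleSystem:
    """Random charged test system with a guaranteed minimum separation."""
    gen = np.random.default_rng(seed)
    while True:
        pos = gen.uniform(0.0, box, (n, 3))
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.floor(d / box + 0.5)
        r = np.sqrt((d * d).sum(-1)) + np.eye(n) * box
        if r.min() > min_sep:
            break
    charges = gen.choice([-1.0, 0.0, 1.0, 4.0], n)
    bonds, angles = ff.ring_topology(n_mono)
    return ff.ParticleSystem(pos, np.zeros((n, 3)), charges,
                             np.array(["X"] * n), n_mono, box, bonds, angles)


@pytest.fixture
def ff_params():
    return ff.ForceFieldParams(bending=5.0, debye=3.0, r_cut_dh=15.0)
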