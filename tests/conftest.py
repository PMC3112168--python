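import numpy as np
import pytest

from raftpuncta.containers import Particle, ParticleSet
from raftpuncta import synthetic_data as sd


@pytest.fixture
def worked_example_set() -> ParticleSet:
    """4 particles of 10 px² plus 1 of 60 px²: C_t = 100 px²."""
    particles = [Particle(x=10.0 * i + 5, y=20.0, area=10.0) for i in range(4)]
    particles.append(Particle(x=60.0, y=60.0, area=60.0))
    return ParticleSet(particles=particles, shape=(100, 100))


@pytest.fixture
def many_small_set() -> ParticleSet:
    """60 particles of 1 px² plus 4 of 10 px²: C_t = 100 px²."""
    particles = [
        Particle(x=float(5 + (i % 10) * 9), y=float(5 + (i // 10) * 9), area=1.0)
        for i in range(60)
    ]
    particles += [Particle(x=10.0 * i + 7, y=80.0, area=10.0) for i in range(4)]
    return ParticleSet(particles=particles, shape=(100, 100))


@pytest.fixture
def preset_groups():
    return sd.preset_alpha2delta_groups()


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
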