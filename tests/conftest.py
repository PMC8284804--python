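"""Shared fixtures: small packed systems reused across test modules."""

import numpy as np
import pytest

from agf.packing import (build_neighbor_list, generate_initial_packing,
                         mark_active_region, relax)
from agf.system import InteractionModel, ParticleSystem


@pytest.fixture(scope="session")
def model():
    return InteractionModel()


@pytest.fixture(scope="session")
def small_system(model):
    """100-particle jammed packing with an active stripe (read-only)."""
    system = generate_initial_packing(100, 1.1, seed=11, model=model)
    mark_active_region(system, 4.0)
    build_neighbor_list(system, model.neighbor_cutoff)
    relax(system, model)
    return system


@pytest.fixture(scope="session")
def medium_system(model):
    """400-particle jammed packing with the 12-wide stripe (read-only)."""
    system = generate_initial_packing(400, 1.1, seed=5, model=model)
    mark_active_region(system, 8.0)
    build_neighbor_list(system, model.neighbor_cutoff)
    relax(system, model)
    return system


def two_particle_system(r, d1=1.0, d2=1.0, connected=True, box=20.0):
    """Two particles at separation r along x, optionally connected."""
    pairs = np.array([[0, 1]]) if connected else np.empty((0, 2), dtype=int)
    return ParticleSystem(
        positions=np.array([[box / 2 - r / 2, box / 2],
                            [box / 2 + r / 2, box / 2]]),
        diameters=np.array([d1, d2]), box=(box, box),
        neighbor_pairs=pairs.astype(np.int64))


def three_particle_line(r, box=20.0):
    """Middle particle flanked at +-r along x, all connected, unit diameters."""
    pairs = np.array([[0, 1], [0, 2]], dtype=np.int64)
    return ParticleSystem(
        positions=np.array([[box / 2, box / 2],
                            [box / 2 - r, box / 2],
                            [box / 2 + r, box / 2]]),
        diameters=np.ones(3), box=(box, box), neighbor_pairs=pairs)
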