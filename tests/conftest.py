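"""Shared fixtures: toy trajectories on disk, small synthetic systems, and a
CHARMM-dialect parameter snippet. Everything is generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from castelo.synthetic import (
    SubtypeBlock,
    SyntheticSpec,
    generate_contact_system,
    generate_toy_trajectory,
)

TOY_PRM = """\
* toy nonbonded parameters
*

NONBONDED nbxmod  5 atom cdiel fshift vatom vdistance vfswitch -
cutnb 14.0 ctofnb 12.0 ctonnb 10.0 eps 1.0 e14fac 1.0 wmin 1.5

CT     0.0  -0.0780    2.0500 ! aliphatic carbon
CT2    0.0  -0.0800    2.0100 ! close to CT: same subtype at 10%
C      0.0  -0.1100    2.0000 ! carbonyl carbon (toy ligand atoms read as C)
OH1    0.0  -0.1521    1.7700 ! hydroxyl oxygen
HA     0.0  -0.0220    1.3200 ! nonpolar hydrogen
N      0.0  -0.2000    1.8500 ! amide nitrogen

BONDS
CT CT 222.5 1.53

END
"""


@pytest.fixture(scope="session")
def toy_prm_text() -> str:
    return TOY_PRM


@pytest.fixture(scope="session")
def one_state_traj(tmp_path_factory):
    """(topology, coordinates) paths of a 10-frame single-pose toy system."""
    out = tmp_path_factory.mktemp("one_state")
    return generate_toy_trajectory(out, n_frames=10, two_state=False, seed=3)


@pytest.fixture(scope="session")
def two_state_traj(tmp_path_factory):
    """(topology, coordinates) paths of a 10-frame two-pose toy system."""
    out = tmp_path_factory.mktemp("two_state")
    return generate_toy_trajectory(out, n_frames=10, two_state=True, seed=4)


@pytest.fixture(scope="session")
def small_system():
    """Small planted contact system: 2 stable + 1 flicker subtype, T=400.

    The coarse 250 ps sampling keeps the dominant mode above the 50 ns
    stability threshold at this reduced frame count.
    """
    spec = SyntheticSpec(
        T=400,
        M=96,
        blocks=(
            SubtypeBlock(0, n_atoms=2, behavior="stable"),
            SubtypeBlock(1, n_atoms=2, behavior="stable"),
            SubtypeBlock(2, n_atoms=2, behavior="flicker", flip_rate=0.5),
        ),
        regime_changes=(250,),
        frame_interval_ps=250.0,
        seed=11,
    )
    return generate_contact_system(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
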