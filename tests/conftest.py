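import numpy as np
import pytest

from pdmslab import md, templates
from pdmslab.builder import assemble_system, pack_nonoverlapping
from pdmslab.parameters import default_forcefield
from pdmslab.system import Molecule, State, Topology


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def lj_fluid(n_side: int, spacing: float = 5.0, kind: str = "CH3",
             mass: float = 15.035) -> State:
    """Simple-cubic lattice of single LJ sites in a periodic box."""
    n = n_side**3
    pos = np.array([
        [i * spacing, j * spacing, k * spacing]
        for i in range(n_side) for j in range(n_side) for k in range(n_side)
    ], dtype=float) + 0.5 * spacing
    top = Topology(
        kinds=[kind] * n, masses=np.full(n, mass), charges=np.zeros(n),
        molecules=[Molecule("lj", np.array([i])) for i in range(n)],
    )
    return State(topology=top, positions=pos, velocities=np.zeros((n, 3)),
                 box=np.array([n_side * spacing] * 3),
                 periodic=np.array([True, True, True]))


@pytest.fixture(scope="session")
def water_box(ff):
    """32 rigid SPC waters, packed and relaxed (session-cached)."""
    box = np.array([10.7] * 3)
    placements = pack_nonoverlapping(
        [(templates.water(), 32)],
        (np.zeros(3) + 0.3, box - 0.3),
        min_dist=1.9, seed=7, box=box,
        periodic=np.array([True, True, True]),
    )
    state = assemble_system(placements, box)
    return md.minimize(state, ff, max_steps=200, f_tol=20.0)


@pytest.fixture(scope="session")
def pdms_box(ff):
    """10 PDMS n=1 oligomers at roughly the experimental liquid density."""
    length = (10 * 236.53 * 1.66054 / 0.85) ** (1 / 3)
    box = np.array([length] * 3)
    placements = pack_nonoverlapping(
        [(templates.pdms_oligomer(1), 10)],
        (np.zeros(3) + 0.2, box - 0.2),
        min_dist=2.0, seed=3, box=box,
        periodic=np.array([True, True, True]),
    )
    state = assemble_system(placements, box)
    return md.minimize(state, ff, max_steps=300, f_tol=10.0)
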