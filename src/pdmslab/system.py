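"""In-memory containers: topology, simulation state, trajectories.

A :class:`Topology` is a flat, array-oriented description of all sites in
the box (kind names, masses, charges), the grouping of sites into
molecules, and the bonded terms connecting them.  :class:`State` adds
positions/velocities/box, and :class:`Trajectory` is a time-ordered list
of :class:`Frame` objects sharing one topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units

__all__ = [
    "Molecule",
    "Topology",
    "Wall",
    "State",
    "Frame",
    "Trajectory",
]


@dataclass
class Molecule:
    """A contiguous group of sites belonging to one chemical species."""

    species: str
    sites: np.ndarray  # int indices into the site arrays

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=int)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class Topology:
    """Site kinds, molecules and bonded connectivity for one system."""

    kinds: list[str]                      # per-site kind name
    masses: np.ndarray                    # per-site, amu
    charges: np.ndarray                   # per-site, e
    molecules: list[Molecule] = field(default_factory=list)
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    angles: list[tuple[int, int, int, str]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, str]] = field(default_factory=list)
    # rigid (SHAKE) constraints: (i, j, target distance A)
    constraints: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.kinds)
        if self.masses.shape != (n,) or self.charges.shape != (n,):
            raise ValueError("masses/charges must have one entry per site")

    @property
    def n_sites(self) -> int:
        return len(self.kinds)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def total_mass(self) -> float:
        return float(self.masses.sum())

    def species_molecules(self, species: str) -> list[Molecule]:
        return [m for m in self.molecules if m.species == species]

    def molecule_index_of_site(self) -> np.ndarray:
        """Per-site molecule index (-1 for sites outside any molecule)."""
        out = np.full(self.n_sites, -1, dtype=int)
        for im, mol in enumerate(self.molecules):
            out[mol.sites] = im
        return out

    def validate(self) -> None:
        n = self.n_sites
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise IndexError(f"bond references missing site ({i},{j})")
        for idx in self.angles:
            if any(not (0 <= k < n) for k in idx[:3]):
                raise IndexError(f"angle references missing site {idx[:3]}")
        for idx in self.dihedrals:
            if any(not (0 <= k < n) for k in idx[:4]):
                raise IndexError(f"dihedral references missing site {idx[:4]}")
        for mol in self.molecules:
            if mol.n_sites and (mol.sites.min() < 0 or mol.sites.max() >= n):
                raise IndexError(f"molecule {mol.species} references missing site")


@dataclass
class Wall:
    """Flat repulsive wall normal to x, acting on selected species only.

    The wall is a WCA-style purely repulsive truncated/shifted LJ in the
    distance between a site and the wall plane.  ``side=+1`` pushes sites
    toward larger x (a wall at the low-x end), ``side=-1`` the reverse.
    """

    x0: float
    side: int                      # +1: wall below the fluid; -1: above
    epsilon: float = 0.2           # kcal/mol
    sigma: float = 3.0             # A
    species: frozenset[str] | None = None   # None -> acts on every species

    def applies_to(self, species: str) -> bool:
        return self.species is None or species in self.species


@dataclass
class State:
    """Topology plus instantaneous coordinates, box and walls."""

    topology: Topology
    positions: np.ndarray            # (N,3) A
    velocities: np.ndarray           # (N,3) A/fs
    box: np.ndarray                  # (3,) A, orthorhombic
    periodic: np.ndarray             # (3,) bool
    walls: list[Wall] = field(default_factory=list)
    # decorative/frozen sites (e.g. FCC wall atoms); indices into topology
    frozen: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.positions = np.array(self.positions, dtype=float)
        self.velocities = np.array(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        self.frozen = np.asarray(self.frozen, dtype=int)
        n = self.topology.n_sites
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be ({n},3)")
        if self.velocities.shape != (n, 3):
            raise ValueError(f"velocities must be ({n},3)")

    def copy(self) -> "State":
        return State(
            topology=self.topology,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box.copy(),
            periodic=self.periodic.copy(),
            walls=list(self.walls),
            frozen=self.frozen.copy(),
        )

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def density(self) -> float:
        """Mass density in g/cm^3."""
        return self.topology.total_mass() / self.volume * units.AMU_A3_TO_G_CM3

    def kinetic_energy(self) -> float:
        """Kinetic energy, kcal/mol."""
        m = self.topology.masses
        return 0.5 * units.MVV2E * float(np.sum(m[:, None] * self.velocities**2))

    def n_dof(self) -> int:
        """Translational degrees of freedom (3N - constraints - frozen - COM)."""
        n_free = self.topology.n_sites - len(self.frozen)
        dof = 3 * n_free - len(self.topology.constraints) - 3
        return max(dof, 1)

    def temperature(self) -> float:
        """Instantaneous kinetic temperature, K."""
        return 2.0 * self.kinetic_energy() / (self.n_dof() * units.KB)


@dataclass
class Frame:
    """One trajectory snapshot."""

    step: int
    time: float                     # fs
    positions: np.ndarray           # (N,3)
    box: np.ndarray                 # (3,)
    temperature: float | None = None
    potential_energy: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)


@dataclass
class Trajectory:
    """Time-ordered frames over a fixed topology.

    ``unwrapped`` marks coordinates that are continuous in time (no
    periodic jumps), which mean-squared-displacement analysis requires.
    """

    topology: Topology
    frames: list[Frame] = field(default_factory=list)
    unwrapped: bool = False

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def positions_array(self) -> np.ndarray:
        """(n_frames, N, 3) stacked coordinates."""
        return np.stack([f.positions for f in self.frames])
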