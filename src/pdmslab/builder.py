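"""System construction: oligomer mixtures, packing, walls, slab geometry.

The slab layout along the non-periodic x axis is

    wall | gap | water | PDMS | water | gap | wall

with y and z periodic.  For the polymer-only annealing stage the water
widths are zero and the gaps are vacuum layers.  Packing re-implements
the usual random non-overlapping insertion (seeded, deterministic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import PackingError, ParameterError
from .system import Molecule, State, Topology, Wall
from .templates import (
    MoleculeTemplate,
    ORGANIC_TEMPLATES,
    pdms_oligomer,
    water,
)

__all__ = [
    "SlabSpec",
    "LoadingPlan",
    "build_pdms_oligomer",
    "build_mixture_80_20",
    "organics_at_saturation",
    "pack_nonoverlapping",
    "assemble_system",
    "build_fcc_wall",
    "build_slab_system",
]

# spec'd oligomer constructor lives in templates; re-export under the
# builder-facing name
build_pdms_oligomer = pdms_oligomer


@dataclass
class SlabSpec:
    """Slab geometry along x (A).  x extent is derived from the parts."""

    pdms_width: float = 28.0
    water_width: float = 48.0        # per side; 0 for the annealing stage
    edge_gap: float = 2.0            # wall-to-fluid margin / vacuum layer
    ly: float = 40.0
    lz: float = 40.0
    wall_lattice_const: float = 3.92
    walls: bool = True

    @property
    def lx(self) -> float:
        return 2 * self.edge_gap + 2 * self.water_width + self.pdms_width

    @property
    def box(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def periodic(self) -> np.ndarray:
        # x non-periodic when walls bound it
        return np.array([not self.walls, True, True])

    def pdms_region(self) -> tuple[float, float]:
        x0 = self.edge_gap + self.water_width
        return (x0, x0 + self.pdms_width)

    def water_regions(self) -> list[tuple[float, float]]:
        if self.water_width <= 0:
            return []
        lo, hi = self.pdms_region()
        return [(self.edge_gap, lo), (hi, self.lx - self.edge_gap)]

    def validate(self) -> None:
        if self.pdms_width <= 0 or self.ly <= 0 or self.lz <= 0:
            raise ParameterError("slab widths must be positive")
        if self.water_width < 0 or self.edge_gap < 0:
            raise ParameterError("water width and edge gap must be >= 0")
        parts = 2 * self.edge_gap + 2 * self.water_width + self.pdms_width
        if not math.isclose(parts, self.lx):
            raise ParameterError("x components must sum to the box length")


@dataclass
class LoadingPlan:
    """Species inventory for a slab system."""

    n_water: int = 0
    n_pdms_n1: int = 0
    n_pdms_n2: int = 0
    organic: str | None = None
    n_organic: int = 0
    solubility_mol_pct: float | None = None
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for label, count in [("n_water", self.n_water),
                             ("n_pdms_n1", self.n_pdms_n1),
                             ("n_pdms_n2", self.n_pdms_n2),
                             ("n_organic", self.n_organic)]:
            if count < 0:
                raise ParameterError(f"{label} must be >= 0")
        if self.solubility_mol_pct is not None:
            limit = organics_at_saturation(self.solubility_mol_pct, self.n_water)
            if self.n_organic > limit:
                raise ParameterError(
                    f"n_organic {self.n_organic} exceeds the solubility-implied "
                    f"maximum {limit}"
                )


def build_mixture_80_20(n1_count: int, n2_count: int):
    """Molecule list for the n=1 / n=2 oligomer mixture and its weight split.

    Returns ``(molecules, weight_fraction_n1)``; the fraction is NaN for
    an empty request.  75 n=1 + 14 n=2 gives the 80:20-by-weight blend
    matched to the 0.825 g/cm^3 coating density.
    """
    if n1_count < 0 or n2_count < 0:
        raise ParameterError("counts must be >= 0")
    t1, t2 = pdms_oligomer(1), pdms_oligomer(2)
    molecules = [t1] * n1_count + [t2] * n2_count
    m1 = n1_count * t1.molecular_mass
    m2 = n2_count * t2.molecular_mass
    fraction = m1 / (m1 + m2) if (m1 + m2) > 0 else float("nan")
    return molecules, fraction


def organics_at_saturation(solubility_mol_pct: float, n_water: int) -> int:
    """Organic count at the aqueous solubility limit.

    Mole-percent is taken relative to the water+organic total, so the
    count is floor(n_water * s / (100 - s)).
    """
    s = solubility_mol_pct
    if not (0 <= s < 100):
        raise ParameterError("solubility mol % must be in [0, 100)")
    return int(math.floor(n_water * s / (100.0 - s)))


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

def pack_nonoverlapping(
    requests: list[tuple[MoleculeTemplate, int]],
    region: tuple[np.ndarray, np.ndarray],
    min_dist: float = 2.0,
    seed: int | np.random.Generator = 0,
    box: np.ndarray | None = None,
    periodic: np.ndarray | None = None,
    existing: np.ndarray | None = None,
    max_attempts: int = 2000,
) -> list[tuple[MoleculeTemplate, np.ndarray]]:
    """Place molecules with random positions/orientations, no overlaps.

    All inter-molecular site pairs end up >= ``min_dist`` apart (under
    minimum image when ``box``/``periodic`` are given) and all sites stay
    inside ``region``.  Deterministic for a fixed seed.  Raises
    :class:`PackingError` (carrying the achieved count) when insertion
    keeps failing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed))
    lo = np.asarray(region[0], float)
    hi = np.asarray(region[1], float)
    if np.any(hi <= lo):
        raise ParameterError("empty packing region")
    volume = float(np.prod(hi - lo))
    n_sites_req = sum(t.n_sites * c for t, c in requests)
    # close-packing bound for spheres of diameter min_dist
    if n_sites_req * (4.0 / 3.0) * math.pi * (min_dist / 2) ** 3 > 0.7405 * volume:
        raise PackingError(
            f"{n_sites_req} sites at min_dist {min_dist} A cannot fit in "
            f"{volume:.0f} A^3", achieved=0,
        )

    placed_sites: list[np.ndarray] = (
        [] if existing is None else [np.asarray(existing, float)])
    placements: list[tuple[MoleculeTemplate, np.ndarray]] = []
    tree: cKDTree | None = None
    tree_stale = True

    def images(pts: np.ndarray) -> np.ndarray:
        """Replicate points into neighbour images on periodic axes."""
        if box is None or periodic is None:
            return pts
        out = [pts]
        for ax in range(3):
            if periodic[ax]:
                new = []
                for arr in out:
                    for shift in (-box[ax], box[ax]):
                        moved = arr.copy()
                        moved[:, ax] += shift
                        new.append(moved)
                out.extend(new)
        return np.vstack(out)

    achieved = 0
    for template, count in requests:
        for _ in range(count):
            ok = False
            for _attempt in range(max_attempts):
                rot = Rotation.random(random_state=rng).as_matrix()
                coords = template.coords @ rot.T
                span_lo = coords.min(axis=0)
                span_hi = coords.max(axis=0)
                room = (hi - span_hi) - (lo - span_lo)
                if np.any(room <= 0):
                    continue
                com = lo - span_lo + rng.random(3) * room
                sites = coords + com
                if placed_sites:
                    if tree is None or tree_stale:
                        tree = cKDTree(images(np.vstack(placed_sites)))
                        tree_stale = False
                    if tree.query_ball_point(sites, min_dist,
                                             return_length=True).sum() > 0:
                        continue
                placed_sites.append(sites)
                tree_stale = True
                placements.append((template, sites))
                achieved += 1
                ok = True
                break
            if not ok:
                raise PackingError(
                    f"could not place molecule {achieved + 1} of "
                    f"{sum(c for _, c in requests)} after {max_attempts} "
                    f"attempts", achieved=achieved,
                )
    return placements


def assemble_system(
    placements: list[tuple[MoleculeTemplate, np.ndarray]],
    box: np.ndarray,
    periodic=(True, True, True),
    walls: list[Wall] | None = None,
    wall_sites: np.ndarray | None = None,
) -> State:
    """Merge placed molecules (plus optional frozen wall atoms) into a State."""
    kinds: list[str] = []
    charges: list[float] = []
    masses: list[float] = []
    molecules: list[Molecule] = []
    bonds, angles, dihedrals, constraints = [], [], [], []
    coords: list[np.ndarray] = []
    offset = 0
    for template, sites in placements:
        n = template.n_sites
        kinds.extend(template.kinds)
        charges.extend(template.charges.tolist())
        masses.extend(template.masses.tolist())
        molecules.append(Molecule(template.name, np.arange(offset, offset + n)))
        bonds.extend((i + offset, j + offset, t) for i, j, t in template.bonds)
        angles.extend((i + offset, j + offset, k + offset, t)
                      for i, j, k, t in template.angles)
        dihedrals.extend((i + offset, j + offset, k + offset, l + offset, t)
                         for i, j, k, l, t in template.dihedrals)
        constraints.extend((i + offset, j + offset, d)
                           for i, j, d in template.constraints)
        coords.append(sites)
        offset += n
    frozen = np.empty(0, dtype=int)
    if wall_sites is not None and len(wall_sites):
        n_w = len(wall_sites)
        kinds.extend(["WALL"] * n_w)
        charges.extend([0.0] * n_w)
        masses.extend([195.08] * n_w)
        molecules.append(Molecule("wall", np.arange(offset, offset + n_w)))
        coords.append(np.asarray(wall_sites, float))
        frozen = np.arange(offset, offset + n_w)
        offset += n_w
    topology = Topology(
        kinds=kinds, masses=np.array(masses), charges=np.array(charges),
        molecules=molecules, bonds=bonds, angles=angles, dihedrals=dihedrals,
        constraints=constraints,
    )
    topology.validate()
    positions = np.vstack(coords) if coords else np.zeros((0, 3))
    return State(
        topology=topology,
        positions=positions,
        velocities=np.zeros_like(positions),
        box=np.asarray(box, float),
        periodic=np.asarray(periodic, bool),
        walls=walls or [],
        frozen=frozen,
    )


def build_fcc_wall(x0: float, ly: float, lz: float,
                   lattice_const: float = 3.92) -> np.ndarray:
    """Single-layer FCC(100) wall patch at plane x = x0 (frozen sites)."""
    a = lattice_const
    ny = max(int(round(ly / a)), 1)
    nz = max(int(round(lz / a)), 1)
    pts = []
    for iy in range(ny):
        for iz in range(nz):
            pts.append([x0, iy * a, iz * a])
            pts.append([x0, (iy + 0.5) * a, (iz + 0.5) * a])
    return np.array(pts)


def build_slab_system(
    spec: SlabSpec,
    loading: LoadingPlan,
    seed: int = 0,
    min_dist: float = 2.0,
    organic_buffer: float = 10.0,
) -> State:
    """Construct the wall | water | PDMS | water | wall slab of the study.

    PDMS oligomers go into the central region, SPC water into the two
    flanking slabs, and the organics into the water within
    ``organic_buffer`` A of the PDMS interface (starting them near the
    polymer shortens the approach to partitioning equilibrium).  The
    walls repel PDMS only; water and organics may pass.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    pdms_species = frozenset({"pdms-n1", "pdms-n2", "pdms-n3"})
    walls = []
    wall_sites = None
    if spec.walls:
        walls = [
            Wall(x0=0.0, side=+1, species=pdms_species),
            Wall(x0=spec.lx, side=-1, species=pdms_species),
        ]
        wall_sites = np.vstack([
            build_fcc_wall(0.0, spec.ly, spec.lz, spec.wall_lattice_const),
            build_fcc_wall(spec.lx, spec.ly, spec.lz, spec.wall_lattice_const),
        ])

    margin = 0.5 * min_dist

    def region(x_lo, x_hi):
        return (np.array([x_lo, 0.0, 0.0]),
                np.array([x_hi, spec.ly, spec.lz]))

    placements = []
    occupied: list[np.ndarray] = []

    def pack_into(requests, reg):
        nonlocal placements, occupied
        existing = np.vstack(occupied) if occupied else None
        new = pack_nonoverlapping(
            requests, reg, min_dist=min_dist, seed=rng,
            box=spec.box, periodic=spec.periodic, existing=existing,
        )
        placements.extend(new)
        occupied.extend(sites for _, sites in new)

    # PDMS slab
    x_lo, x_hi = spec.pdms_region()
    pdms_requests = []
    if loading.n_pdms_n1:
        pdms_requests.append((pdms_oligomer(1), loading.n_pdms_n1))
    if loading.n_pdms_n2:
        pdms_requests.append((pdms_oligomer(2), loading.n_pdms_n2))
    if pdms_requests:
        pack_into(pdms_requests, region(x_lo + margin, x_hi - margin))

    # organics adjacent to the PDMS interfaces, then water elsewhere
    w_template = water()
    organic = None
    if loading.organic is not None and loading.n_organic > 0:
        try:
            organic = ORGANIC_TEMPLATES[loading.organic]()
        except KeyError:
            raise ParameterError(
                f"unknown organic species {loading.organic!r}") from None
    for i, (w_lo, w_hi) in enumerate(spec.water_regions()):
        near_pdms = (
            (max(w_hi - organic_buffer, w_lo), w_hi) if i == 0
            else (w_lo, min(w_lo + organic_buffer, w_hi))
        )
        if organic is not None:
            n_here = loading.n_organic // 2 + (loading.n_organic % 2 if i == 0 else 0)
            if n_here:
                pack_into([(organic, n_here)], region(*near_pdms))
        n_water_here = loading.n_water // 2 + (loading.n_water % 2 if i == 0 else 0)
        if n_water_here:
            pack_into([(w_template, n_water_here)],
                      region(w_lo + margin, w_hi - margin))

    return assemble_system(
        placements, spec.box, periodic=spec.periodic,
        walls=walls, wall_sites=wall_sites,
    )
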