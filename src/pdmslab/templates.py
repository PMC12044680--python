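"""Molecule templates: rigid SPC water, PDMS oligomers, the five organics.

Template geometries are idealized internal coordinates good enough for
packing and as MD starting points; bonded terms relax them during
dynamics.  Charges are assigned per site and sum to zero for every
template.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .parameters import SPC_ANGLE_DEG, SPC_HH, SPC_OH

__all__ = [
    "MoleculeTemplate",
    "water",
    "pdms_oligomer",
    "phenol",
    "chlorophenol",
    "guaiacol",
    "benzyl_alcohol",
    "phenethyl_alcohol",
    "ORGANIC_TEMPLATES",
]

KIND_MASS = {
    "Si": 28.0855, "OSi": 15.999, "CH3": 15.035,
    "OW": 15.999, "HW": 1.008,
    "CA": 12.011, "HA": 1.008, "OH": 15.999, "HO": 1.008,
    "CL": 35.453, "CT": 12.011, "HC": 1.008, "OS": 15.999,
    "WALL": 195.08,
}


@dataclass
class MoleculeTemplate:
    """One species: site kinds, charges, internal coordinates, topology."""

    name: str
    kinds: list[str]
    charges: np.ndarray
    coords: np.ndarray                      # (n, 3) A, centered on the COM
    bonds: list[tuple[int, int, str]] = field(default_factory=list)
    angles: list[tuple[int, int, int, str]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, str]] = field(default_factory=list)
    constraints: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.kinds) != len(self.coords) or len(self.kinds) != len(self.charges):
            raise ParameterError(
                f"template {self.name}: kinds/charges/coords lengths disagree"
            )
        # center internal coordinates on the center of mass
        m = self.masses
        self.coords = self.coords - np.average(self.coords, axis=0, weights=m)

    @property
    def n_sites(self) -> int:
        return len(self.kinds)

    @property
    def masses(self) -> np.ndarray:
        return np.array([KIND_MASS[k] for k in self.kinds])

    @property
    def molecular_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def radius(self) -> float:
        """Largest site distance from the COM (packing envelope)."""
        return float(np.linalg.norm(self.coords, axis=1).max())


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _perp(v):
    """Some unit vector perpendicular to v."""
    v = _unit(v)
    trial = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, trial))


def _complete_tetrahedron(existing: list[np.ndarray]) -> list[np.ndarray]:
    """Directions filling a tetrahedral center given 1 or 2 bond directions."""
    th = math.radians(109.47)
    if len(existing) == 1:
        d = _unit(existing[0])
        p = _perp(d)
        q = np.cross(d, p)
        out = []
        for k in range(3):
            az = 2 * math.pi * k / 3
            out.append(
                math.cos(th) * d
                + math.sin(th) * (math.cos(az) * p + math.sin(az) * q)
            )
        return out
    if len(existing) == 2:
        d1, d2 = _unit(existing[0]), _unit(existing[1])
        b = -_unit(d1 + d2)
        n = _unit(np.cross(d1, d2))
        half = math.radians(109.47 / 2)
        return [
            math.cos(half) * b + math.sin(half) * n,
            math.cos(half) * b - math.sin(half) * n,
        ]
    raise ParameterError("need 1 or 2 existing directions")


# ---------------------------------------------------------------------------
# water
# ---------------------------------------------------------------------------

def water() -> MoleculeTemplate:
    """Rigid SPC water (O-H 1.0 A, H-O-H 109.47 deg, SHAKE constraints)."""
    half = math.radians(SPC_ANGLE_DEG / 2)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [SPC_OH * math.sin(half), SPC_OH * math.cos(half), 0.0],
        [-SPC_OH * math.sin(half), SPC_OH * math.cos(half), 0.0],
    ])
    return MoleculeTemplate(
        name="water",
        kinds=["OW", "HW", "HW"],
        charges=[-0.82, 0.41, 0.41],
        coords=coords,
        constraints=[(0, 1, SPC_OH), (0, 2, SPC_OH), (1, 2, SPC_HH)],
    )


# ---------------------------------------------------------------------------
# PDMS oligomers
# ---------------------------------------------------------------------------

def pdms_oligomer(n: int) -> MoleculeTemplate:
    """Linear PDMS oligomer with n repeat units (n = 1, 2 or 3).

    United-atom: (n+2) Si, (n+1) backbone O, (2n+6) CH3 sites.  n=1 is
    octamethyltrisiloxane, n=2 decamethyltetrasiloxane, n=3
    dodecamethylpentasiloxane.
    """
    if n not in (1, 2, 3):
        raise ParameterError(f"PDMS repeat count n must be 1, 2 or 3, got {n}")
    d_sio, d_sic = 1.64, 1.90
    # zig-zag backbone Si-O-Si-O-...-Si in the xy plane
    half = math.radians(26.5)  # backbone vertex angle ~127 deg
    n_backbone = 2 * (n + 2) - 1
    backbone = np.zeros((n_backbone, 3))
    direction = np.array([math.cos(half), math.sin(half), 0.0])
    for i in range(1, n_backbone):
        backbone[i] = backbone[i - 1] + d_sio * direction
        direction = direction * np.array([1.0, -1.0, 1.0])

    kinds: list[str] = []
    charges: list[float] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int, str]] = []
    angles: list[tuple[int, int, int, str]] = []
    dihedrals: list[tuple[int, int, int, int, str]] = []

    si_index: list[int] = []
    o_index: list[int] = []
    for i in range(n_backbone):
        if i % 2 == 0:  # Si
            terminal = i in (0, n_backbone - 1)
            kinds.append("Si")
            charges.append(0.15 if terminal else 0.30)
            si_index.append(len(coords))
        else:  # backbone O
            kinds.append("OSi")
            charges.append(-0.30)
            o_index.append(len(coords))
        coords.append(backbone[i])

    # backbone bonds/angles/dihedrals
    bb = list(range(n_backbone))
    for i in range(n_backbone - 1):
        bonds.append((bb[i], bb[i + 1], "SiO"))
    for i in range(1, n_backbone - 1):
        angles.append((bb[i - 1], bb[i], bb[i + 1],
                       "SiOSi" if i % 2 == 1 else "OSiO"))
    for i in range(n_backbone - 3):
        dihedrals.append((bb[i], bb[i + 1], bb[i + 2], bb[i + 3], "SIOX"))

    # methyls: 3 on terminal Si, 2 on inner Si
    for pos_in_chain, si in zip(range(0, n_backbone, 2), si_index):
        neighbors = []
        if pos_in_chain > 0:
            neighbors.append(backbone[pos_in_chain - 1] - backbone[pos_in_chain])
        if pos_in_chain < n_backbone - 1:
            neighbors.append(backbone[pos_in_chain + 1] - backbone[pos_in_chain])
        for d in _complete_tetrahedron(neighbors):
            c_idx = len(coords)
            kinds.append("CH3")
            charges.append(0.0)
            coords.append(backbone[pos_in_chain] + d_sic * d)
            bonds.append((si, c_idx, "SiC"))
        # angles around this Si
        attached = [b for b in bonds if b[2] == "SiC" and b[0] == si]
        carbons = [b[1] for b in attached]
        for a in range(len(carbons)):
            for b in range(a + 1, len(carbons)):
                angles.append((carbons[a], si, carbons[b], "CSiC"))
        ox_neighbors = [bb[pos_in_chain + k] for k in (-1, 1)
                        if 0 <= pos_in_chain + k < n_backbone]
        for c in carbons:
            for o in ox_neighbors:
                angles.append((c, si, o, "CSiO"))

    names = {1: "pdms-n1", 2: "pdms-n2", 3: "pdms-n3"}
    return MoleculeTemplate(
        name=names[n], kinds=kinds, charges=charges, coords=np.array(coords),
        bonds=bonds, angles=angles, dihedrals=dihedrals,
    )


# ---------------------------------------------------------------------------
# organics (all-atom, idealized geometries)
# ---------------------------------------------------------------------------

_RING_R = 1.40
_D_CH = 1.08
_D_CO = 1.364
_D_OHH = 0.945
_D_CCL = 1.725
_D_CC = 1.51
_D_CTCT = 1.529
_D_CTH = 1.09
_D_CTO = 1.41


class _Builder:
    """Incremental template assembly with index bookkeeping."""

    def __init__(self, name: str):
        self.name = name
        self.kinds: list[str] = []
        self.charges: list[float] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int, str]] = []
        self.angles: list[tuple[int, int, int, str]] = []
        self.dihedrals: list[tuple[int, int, int, int, str]] = []

    def add(self, kind: str, charge: float, xyz) -> int:
        self.kinds.append(kind)
        self.charges.append(charge)
        self.coords.append(np.asarray(xyz, float))
        return len(self.coords) - 1

    def build(self) -> MoleculeTemplate:
        return MoleculeTemplate(
            name=self.name, kinds=self.kinds, charges=self.charges,
            coords=np.array(self.coords), bonds=self.bonds,
            angles=self.angles, dihedrals=self.dihedrals,
        )


def _ring(b: _Builder, substituted: dict[int, float]):
    """Six aromatic carbons; carbons not in ``substituted`` get -0.115.

    Returns (carbon indices, radial unit vectors).
    """
    idx, radial = [], []
    for i in range(6):
        ang = math.radians(60 * i)
        r = np.array([math.cos(ang), math.sin(ang), 0.0])
        q = substituted.get(i, -0.115)
        idx.append(b.add("CA", q, _RING_R * r))
        radial.append(r)
    for i in range(6):
        b.bonds.append((idx[i], idx[(i + 1) % 6], "CA-CA"))
        b.angles.append((idx[i], idx[(i + 1) % 6], idx[(i + 2) % 6], "CA-CA-CA"))
        b.dihedrals.append((idx[i], idx[(i + 1) % 6], idx[(i + 2) % 6],
                            idx[(i + 3) % 6], "AROM"))
    return idx, radial


def _ring_hydrogens(b: _Builder, idx, radial, skip: set[int]):
    for i in range(6):
        if i in skip:
            continue
        h = b.add("HA", 0.115, np.array(b.coords[idx[i]]) + _D_CH * radial[i])
        b.bonds.append((idx[i], h, "CA-HA"))
        b.angles.append((h, idx[i], idx[(i + 1) % 6], "CA-CA-HA"))
        b.angles.append((h, idx[i], idx[(i - 1) % 6], "CA-CA-HA"))


def _hydroxyl(b: _Builder, parent: int, direction, q_o=-0.585, q_h=0.435,
              d_xo=_D_CO, bond_xo="CA-OH", angle_oh="CA-OH-HO",
              bond_oh="OH-HO"):
    o_pos = np.array(b.coords[parent]) + d_xo * _unit(direction)
    o = b.add("OH", q_o, o_pos)
    b.bonds.append((parent, o, bond_xo))
    # O-H tilted ~109 deg off the X-O axis, in plane
    d = _unit(direction)
    p = _perp(d)
    hdir = math.cos(math.radians(180 - 109)) * d + math.sin(
        math.radians(180 - 109)) * p
    h = b.add("HO", q_h, o_pos + _D_OHH * _unit(hdir))
    b.bonds.append((o, h, bond_oh))
    b.angles.append((parent, o, h, angle_oh))
    return o, h


def phenol() -> MoleculeTemplate:
    b = _Builder("phenol")
    idx, radial = _ring(b, {0: 0.15})
    _ring_hydrogens(b, idx, radial, skip={0})
    o, _ = _hydroxyl(b, idx[0], radial[0])
    b.angles.append((o, idx[0], idx[1], "CA-CA-OH"))
    b.angles.append((o, idx[0], idx[5], "CA-CA-OH"))
    return b.build()


def chlorophenol() -> MoleculeTemplate:
    """2-chlorophenol."""
    b = _Builder("chlorophenol")
    idx, radial = _ring(b, {0: 0.15, 1: 0.18})
    _ring_hydrogens(b, idx, radial, skip={0, 1})
    o, _ = _hydroxyl(b, idx[0], radial[0])
    b.angles.append((o, idx[0], idx[1], "CA-CA-OH"))
    b.angles.append((o, idx[0], idx[5], "CA-CA-OH"))
    cl = b.add("CL", -0.18, np.array(b.coords[idx[1]]) + _D_CCL * radial[1])
    b.bonds.append((idx[1], cl, "CA-CL"))
    b.angles.append((cl, idx[1], idx[0], "CA-CA-CL"))
    b.angles.append((cl, idx[1], idx[2], "CA-CA-CL"))
    return b.build()


def guaiacol() -> MoleculeTemplate:
    """2-methoxyphenol."""
    b = _Builder("guaiacol")
    idx, radial = _ring(b, {0: 0.15, 1: 0.085})
    _ring_hydrogens(b, idx, radial, skip={0, 1})
    o, _ = _hydroxyl(b, idx[0], radial[0])
    b.angles.append((o, idx[0], idx[1], "CA-CA-OH"))
    b.angles.append((o, idx[0], idx[5], "CA-CA-OH"))
    # methoxy: ring-O-CH3
    os_pos = np.array(b.coords[idx[1]]) + _D_CO * radial[1]
    os = b.add("OS", -0.285, os_pos)
    b.bonds.append((idx[1], os, "CA-OS"))
    b.angles.append((os, idx[1], idx[0], "CA-CA-OS"))
    b.angles.append((os, idx[1], idx[2], "CA-CA-OS"))
    d = _unit(radial[1] + _perp(radial[1]))
    ct_pos = os_pos + _D_CTO * d
    ct = b.add("CT", 0.11, ct_pos)
    b.bonds.append((os, ct, "CT-OS"))
    b.angles.append((idx[1], os, ct, "CA-OS-CT"))
    for hd in _complete_tetrahedron([os_pos - ct_pos]):
        h = b.add("HC", 0.03, ct_pos + _D_CTH * hd)
        b.bonds.append((ct, h, "CT-HC"))
        b.angles.append((h, ct, os, "HC-CT-OS"))
    return b.build()


def benzyl_alcohol() -> MoleculeTemplate:
    b = _Builder("benzyl alcohol")
    idx, radial = _ring(b, {0: 0.0})
    _ring_hydrogens(b, idx, radial, skip={0})
    ct_pos = np.array(b.coords[idx[0]]) + _D_CC * radial[0]
    ct = b.add("CT", 0.145, ct_pos)
    b.bonds.append((idx[0], ct, "CA-CT"))
    b.angles.append((ct, idx[0], idx[1], "CA-CA-CT"))
    b.angles.append((ct, idx[0], idx[5], "CA-CA-CT"))
    o_dir = _unit(radial[0] + np.array([0.0, 0.0, 1.0]))
    o, _ = _hydroxyl(b, ct, o_dir, q_o=-0.683, q_h=0.418,
                     d_xo=_D_CTO, bond_xo="CT-OH", angle_oh="CT-OH-HO")
    b.angles.append((idx[0], ct, o, "CA-CT-OH"))
    for hd in _complete_tetrahedron(
        [np.array(b.coords[idx[0]]) - ct_pos, np.array(b.coords[o]) - ct_pos]
    ):
        h = b.add("HC", 0.06, ct_pos + _D_CTH * hd)
        b.bonds.append((ct, h, "CT-HC"))
        b.angles.append((h, ct, idx[0], "CA-CT-HC"))
        b.angles.append((h, ct, o, "HC-CT-OH"))
    return b.build()


def phenethyl_alcohol() -> MoleculeTemplate:
    b = _Builder("phenethyl alcohol")
    idx, radial = _ring(b, {0: 0.0})
    _ring_hydrogens(b, idx, radial, skip={0})
    c1_pos = np.array(b.coords[idx[0]]) + _D_CC * radial[0]
    c1 = b.add("CT", -0.12, c1_pos)
    b.bonds.append((idx[0], c1, "CA-CT"))
    b.angles.append((c1, idx[0], idx[1], "CA-CA-CT"))
    b.angles.append((c1, idx[0], idx[5], "CA-CA-CT"))
    c2_dir = _unit(radial[0] + np.array([0.0, 0.0, 0.9]))
    c2_pos = c1_pos + _D_CTCT * c2_dir
    c2 = b.add("CT", 0.145, c2_pos)
    b.bonds.append((c1, c2, "CT-CT"))
    b.angles.append((idx[0], c1, c2, "CA-CT-CT"))
    o_dir = _unit(c2_dir + np.array([0.0, 0.0, 1.2]))
    o, _ = _hydroxyl(b, c2, o_dir, q_o=-0.683, q_h=0.418,
                     d_xo=_D_CTO, bond_xo="CT-OH", angle_oh="CT-OH-HO")
    b.angles.append((c1, c2, o, "CT-CT-OH"))
    for hd in _complete_tetrahedron(
        [np.array(b.coords[idx[0]]) - c1_pos, c2_pos - c1_pos]
    ):
        h = b.add("HC", 0.06, c1_pos + _D_CTH * hd)
        b.bonds.append((c1, h, "CT-HC"))
        b.angles.append((h, c1, c2, "CT-CT-HC"))
        b.angles.append((h, c1, idx[0], "CA-CT-HC"))
    for hd in _complete_tetrahedron(
        [c1_pos - c2_pos, np.array(b.coords[o]) - c2_pos]
    ):
        h = b.add("HC", 0.06, c2_pos + _D_CTH * hd)
        b.bonds.append((c2, h, "CT-HC"))
        b.angles.append((h, c2, c1, "CT-CT-HC"))
        b.angles.append((h, c2, o, "HC-CT-OH"))
    return b.build()


ORGANIC_TEMPLATES = {
    "phenol": phenol,
    "chlorophenol": chlorophenol,
    "guaiacol": guaiacol,
    "benzyl alcohol": benzyl_alcohol,
    "phenethyl alcohol": phenethyl_alcohol,
}
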