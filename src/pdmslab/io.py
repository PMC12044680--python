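"""File formats: extended XYZ, LAMMPS data/dump, parameter files, CSV.

The package's text formats are all round-trippable:

* extended XYZ trajectories with a ``Lattice=...`` / ``Properties=...``
  comment line carrying step, time, temperature and periodicity; sites
  additionally carry their molecule id and molecule species, so a
  trajectory file alone supports the whole analysis chain.
* LAMMPS data files ("full" atom style, real units) for initial
  configurations, with kind names preserved as comments in the Masses
  section.
* a YAML force-field parameter dialect serializing
  :class:`~pdmslab.forcefield.ForceFieldSpec` losslessly.

Malformed or truncated files raise :class:`~pdmslab.errors.ParseError`
with a line number rather than returning partial data.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError
from .forcefield import BondedTerms, ForceFieldSpec, PairTable, SiteKind
from .system import Frame, Molecule, State, Topology, Trajectory
from .templates import KIND_MASS

__all__ = [
    "write_extxyz",
    "read_extxyz",
    "write_lammps_data",
    "read_lammps_data",
    "write_lammps_dump",
    "read_lammps_dump",
    "write_forcefield",
    "read_forcefield",
    "profile_to_frame",
    "partition_to_frame",
    "msd_to_frame",
]


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_PROPERTIES = "species:S:1:pos:R:3:molid:I:1:molspecies:S:1"


def write_extxyz(path, trajectory: Trajectory) -> None:
    """Write a trajectory in the package's extended-XYZ dialect."""
    top = trajectory.topology
    molid = top.molecule_index_of_site()
    mol_species = np.array(
        [top.molecules[i].species if i >= 0 else "none" for i in molid])
    with open(path, "w") as fh:
        for frame in trajectory:
            lx, ly, lz = frame.box
            meta = (
                f'Lattice="{lx} 0.0 0.0 0.0 {ly} 0.0 0.0 0.0 {lz}" '
                f'Properties={_PROPERTIES} step={frame.step} '
                f'time={frame.time}'
            )
            if frame.temperature is not None:
                meta += f" temperature={frame.temperature}"
            if frame.potential_energy is not None:
                meta += f" potential_energy={frame.potential_energy}"
            meta += f" unwrapped={'T' if trajectory.unwrapped else 'F'}"
            fh.write(f"{top.n_sites}\n{meta}\n")
            for i in range(top.n_sites):
                x, y, z = frame.positions[i]
                sp = mol_species[i].replace(" ", "_")
                fh.write(f"{top.kinds[i]} {x:.8f} {y:.8f} {z:.8f} "
                         f"{molid[i]} {sp}\n")


def _parse_kv(comment: str) -> dict:
    out = {}
    for m in re.finditer(r'(\S+)="([^"]*)"|(\S+)=(\S+)', comment):
        if m.group(1) is not None:
            out[m.group(1)] = m.group(2)
        else:
            out[m.group(3)] = m.group(4)
    return out


def read_extxyz(path) -> Trajectory:
    """Read a trajectory written by :func:`write_extxyz`."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    topology: Topology | None = None
    unwrapped = False
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {lines[i]!r}",
                             line=i + 1) from None
        if i + 1 >= len(lines):
            raise ParseError("missing comment line", line=i + 2)
        meta = _parse_kv(lines[i + 1])
        if "Lattice" not in meta:
            raise ParseError("comment line lacks Lattice=", line=i + 2)
        lat = [float(v) for v in meta["Lattice"].split()]
        box = np.array([lat[0], lat[4], lat[8]])
        if i + 1 + n >= len(lines) + 0 and n > 0 and i + 2 + n > len(lines):
            raise ParseError(
                f"truncated frame: expected {n} atom lines", line=len(lines))
        kinds, positions, molids, mol_sp = [], [], [], []
        for k in range(n):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ParseError(
                    f"truncated frame: expected {n} atom lines", line=ln + 1)
            parts = lines[ln].split()
            if len(parts) < 6:
                raise ParseError("atom line needs 6 fields", line=ln + 1)
            kinds.append(parts[0])
            positions.append([float(parts[1]), float(parts[2]),
                              float(parts[3])])
            molids.append(int(parts[4]))
            mol_sp.append(parts[5].replace("_", " "))
        if topology is None:
            molids_arr = np.asarray(molids)
            molecules = []
            for mid in sorted(set(molids_arr.tolist())):
                sites = np.flatnonzero(molids_arr == mid)
                molecules.append(Molecule(mol_sp[sites[0]], sites))
            topology = Topology(
                kinds=kinds,
                masses=np.array([KIND_MASS.get(k, 1.0) for k in kinds]),
                charges=np.zeros(n),
                molecules=molecules,
            )
        unwrapped = meta.get("unwrapped", "F") == "T"
        frames.append(Frame(
            step=int(meta.get("step", len(frames))),
            time=float(meta.get("time", len(frames))),
            positions=np.array(positions),
            box=box,
            temperature=(float(meta["temperature"])
                         if "temperature" in meta else None),
            potential_energy=(float(meta["potential_energy"])
                              if "potential_energy" in meta else None),
        ))
        i += 2 + n
    if topology is None:
        raise ParseError("empty trajectory file")
    return Trajectory(topology=topology, frames=frames, unwrapped=unwrapped)


# ---------------------------------------------------------------------------
# LAMMPS data
# ---------------------------------------------------------------------------

def write_lammps_data(path, state: State) -> None:
    """Write a LAMMPS data file (atom style full, real units)."""
    top = state.topology
    kind_names = sorted(set(top.kinds))
    kind_id = {k: i + 1 for i, k in enumerate(kind_names)}
    bond_types = sorted({b[2] for b in top.bonds})
    angle_types = sorted({a[3] for a in top.angles})
    dih_types = sorted({d[4] for d in top.dihedrals})
    bond_id = {t: i + 1 for i, t in enumerate(bond_types)}
    angle_id = {t: i + 1 for i, t in enumerate(angle_types)}
    dih_id = {t: i + 1 for i, t in enumerate(dih_types)}
    molid = top.molecule_index_of_site()
    kind_mass = {}
    for k, m in zip(top.kinds, top.masses):
        kind_mass.setdefault(k, m)
    with open(path, "w") as fh:
        fh.write("pdmslab data file\n\n")
        fh.write(f"{top.n_sites} atoms\n")
        fh.write(f"{len(top.bonds)} bonds\n")
        fh.write(f"{len(top.angles)} angles\n")
        fh.write(f"{len(top.dihedrals)} dihedrals\n\n")
        fh.write(f"{len(kind_names)} atom types\n")
        if bond_types:
            fh.write(f"{len(bond_types)} bond types\n")
        if angle_types:
            fh.write(f"{len(angle_types)} angle types\n")
        if dih_types:
            fh.write(f"{len(dih_types)} dihedral types\n")
        fh.write(f"\n0.0 {state.box[0]} xlo xhi\n")
        fh.write(f"0.0 {state.box[1]} ylo yhi\n")
        fh.write(f"0.0 {state.box[2]} zlo zhi\n\n")
        fh.write("Masses\n\n")
        for k in kind_names:
            fh.write(f"{kind_id[k]} {kind_mass[k]} # {k}\n")
        fh.write("\nAtoms # full\n\n")
        for i in range(top.n_sites):
            x, y, z = state.positions[i]
            fh.write(f"{i + 1} {molid[i] + 1} {kind_id[top.kinds[i]]} "
                     f"{top.charges[i]} {x:.8f} {y:.8f} {z:.8f}\n")
        if top.bonds:
            fh.write("\nBonds\n\n")
            for n, (i, j, t) in enumerate(top.bonds, 1):
                fh.write(f"{n} {bond_id[t]} {i + 1} {j + 1}\n")
        if top.angles:
            fh.write("\nAngles\n\n")
            for n, (i, j, k, t) in enumerate(top.angles, 1):
                fh.write(f"{n} {angle_id[t]} {i + 1} {j + 1} {k + 1}\n")
        if top.dihedrals:
            fh.write("\nDihedrals\n\n")
            for n, (i, j, k, l, t) in enumerate(top.dihedrals, 1):
                fh.write(f"{n} {dih_id[t]} {i + 1} {j + 1} {k + 1} {l + 1}\n")


def read_lammps_data(path) -> State:
    """Read a data file written by :func:`write_lammps_data`.

    Bond/angle/dihedral *type names* are not stored in the format, so
    they come back as numeric strings; counts, connectivity, charges and
    coordinates round-trip exactly.
    """
    lines = Path(path).read_text().splitlines()
    counts = {"atoms": 0, "bonds": 0, "angles": 0, "dihedrals": 0}
    box = np.zeros(3)
    kind_of_type: dict[int, str] = {}
    mass_of_type: dict[int, float] = {}
    section = None
    atoms, bonds, angles, dihedrals = [], [], [], []
    for ln, raw in enumerate(lines, 1):
        line = raw.split("#")[0].strip() if "Masses" not in raw else raw.strip()
        comment = raw.split("#")[1].strip() if "#" in raw else None
        if not line and "Masses" not in raw:
            continue
        m = re.match(r"^(\d+)\s+(atoms|bonds|angles|dihedrals)$", line)
        if m:
            counts[m.group(2)] = int(m.group(1))
            continue
        m = re.match(r"^([\d.eE+-]+)\s+([\d.eE+-]+)\s+([xyz])lo\s+[xyz]hi$", line)
        if m:
            axis = "xyz".index(m.group(3))
            box[axis] = float(m.group(2)) - float(m.group(1))
            continue
        if line.startswith("Masses"):
            section = "masses"
            continue
        if line.startswith("Atoms"):
            section = "atoms"
            continue
        if line.startswith("Bonds"):
            section = "bonds"
            continue
        if line.startswith("Angles"):
            section = "angles"
            continue
        if line.startswith("Dihedrals"):
            section = "dihedrals"
            continue
        if re.match(r"^\d+\s+\w+\s+types$", line):
            continue
        parts = line.split()
        try:
            if section == "masses":
                mass_of_type[int(parts[0])] = float(parts[1])
                if comment:
                    kind_of_type[int(parts[0])] = comment
            elif section == "atoms":
                atoms.append((int(parts[0]), int(parts[1]), int(parts[2]),
                              float(parts[3]), float(parts[4]),
                              float(parts[5]), float(parts[6])))
            elif section == "bonds":
                bonds.append((int(parts[2]) - 1, int(parts[3]) - 1, parts[1]))
            elif section == "angles":
                angles.append((int(parts[2]) - 1, int(parts[3]) - 1,
                               int(parts[4]) - 1, parts[1]))
            elif section == "dihedrals":
                dihedrals.append((int(parts[2]) - 1, int(parts[3]) - 1,
                                  int(parts[4]) - 1, int(parts[5]) - 1,
                                  parts[1]))
        except (ValueError, IndexError):
            raise ParseError(f"malformed {section} line", line=ln) from None
    if len(atoms) != counts["atoms"]:
        raise ParseError(
            f"truncated file: header promises {counts['atoms']} atoms, "
            f"found {len(atoms)}")
    for label, found in (("bonds", bonds), ("angles", angles),
                         ("dihedrals", dihedrals)):
        if len(found) != counts[label]:
            raise ParseError(
                f"truncated file: header promises {counts[label]} {label}, "
                f"found {len(found)}")
    atoms.sort(key=lambda a: a[0])
    kinds = [kind_of_type.get(a[2], str(a[2])) for a in atoms]
    masses = np.array([mass_of_type[a[2]] for a in atoms])
    charges = np.array([a[3] for a in atoms])
    positions = np.array([[a[4], a[5], a[6]] for a in atoms])
    molids = np.array([a[1] for a in atoms])
    molecules = [Molecule(str(mid), np.flatnonzero(molids == mid))
                 for mid in sorted(set(molids.tolist()))]
    top = Topology(kinds=kinds, masses=masses, charges=charges,
                   molecules=molecules, bonds=bonds, angles=angles,
                   dihedrals=dihedrals)
    return State(topology=top, positions=positions,
                 velocities=np.zeros_like(positions), box=box,
                 periodic=np.array([True, True, True]))


# ---------------------------------------------------------------------------
# LAMMPS dump
# ---------------------------------------------------------------------------

def write_lammps_dump(path, trajectory: Trajectory) -> None:
    """Minimal LAMMPS dump writer (id type xu yu zu, unwrapped coords)."""
    top = trajectory.topology
    kind_names = sorted(set(top.kinds))
    kind_id = {k: i + 1 for i, k in enumerate(kind_names)}
    with open(path, "w") as fh:
        for frame in trajectory:
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{frame.step}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{top.n_sites}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for ax in range(3):
                fh.write(f"0.0 {frame.box[ax]}\n")
            fh.write("ITEM: ATOMS id type xu yu zu\n")
            for i in range(top.n_sites):
                x, y, z = frame.positions[i]
                fh.write(f"{i + 1} {kind_id[top.kinds[i]]} "
                         f"{x:.8f} {y:.8f} {z:.8f}\n")


def read_lammps_dump(path) -> list[Frame]:
    """Read frames (positions/box/step) from a LAMMPS dump file."""
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ParseError("expected ITEM: TIMESTEP", line=i + 1)
        step = int(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError("expected ITEM: NUMBER OF ATOMS", line=i + 3)
        n = int(lines[i + 3])
        box = np.zeros(3)
        for ax in range(3):
            lo, hi = lines[i + 5 + ax].split()[:2]
            box[ax] = float(hi) - float(lo)
        if not lines[i + 8].startswith("ITEM: ATOMS"):
            raise ParseError("expected ITEM: ATOMS", line=i + 9)
        if i + 9 + n > len(lines):
            raise ParseError(f"truncated dump: expected {n} atoms",
                             line=len(lines))
        rows = []
        for k in range(n):
            parts = lines[i + 9 + k].split()
            rows.append((int(parts[0]), float(parts[2]), float(parts[3]),
                         float(parts[4])))
        rows.sort(key=lambda r: r[0])
        frames.append(Frame(step=step, time=float(step),
                            positions=np.array([r[1:] for r in rows]),
                            box=box))
        i += 9 + n
    return frames


# ---------------------------------------------------------------------------
# force-field parameter files (YAML dialect)
# ---------------------------------------------------------------------------

def write_forcefield(path, ff: ForceFieldSpec) -> None:
    """Serialize a force field to the package's YAML parameter dialect."""
    doc = {
        "cutoff": ff.cutoff,
        "electrostatics": ff.electrostatics,
        "dsf_alpha": ff.dsf_alpha,
        "rf_dielectric": ff.rf_dielectric,
        "coulomb_constant": ff.coulomb_constant,
        "half_harmonic": ff.half_harmonic,
        "scale_14": ff.scale_14,
        "lj_shift": ff.lj_shift,
        "site_kinds": {
            k.name: {"mass": k.mass, "charge": k.charge,
                     "epsilon": k.epsilon, "sigma": k.sigma}
            for k in ff.kinds.values()
        },
        "explicit_pairs": [
            {"kinds": list(key), "epsilon": eps, "sigma": sig}
            for key, (eps, sig) in sorted(ff.pair_table.explicit_pairs.items())
        ],
        "cross_scale": [
            {"kinds": list(key), "factor": fac}
            for key, fac in sorted(ff.pair_table.cross_scale.items())
        ],
        "bonds": {t: {"k": k, "r0": r0}
                  for t, (k, r0) in ff.bonded.bonds.items()},
        "angles": {t: {"k": k, "theta0": th}
                   for t, (k, th) in ff.bonded.angles.items()},
        "dihedrals": {t: list(c) for t, c in ff.bonded.dihedrals.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_forcefield(path) -> ForceFieldSpec:
    """Parse the YAML parameter dialect back into a ForceFieldSpec."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        raise ParseError(str(exc),
                         line=mark.line + 1 if mark else None) from None
    if not isinstance(doc, dict):
        raise ParseError("parameter file must be a mapping")
    try:
        kinds = {
            name: SiteKind(name=name, mass=spec["mass"], charge=spec["charge"],
                           epsilon=spec["epsilon"], sigma=spec["sigma"])
            for name, spec in doc.get("site_kinds", {}).items()
        }
        pairs = PairTable()
        for entry in doc.get("explicit_pairs", []):
            a, b = entry["kinds"]
            pairs.set_pair(a, b, entry["epsilon"], entry["sigma"])
        for entry in doc.get("cross_scale", []):
            a, b = entry["kinds"]
            pairs.set_scale(a, b, entry["factor"])
        bonded = BondedTerms(
            bonds={t: (s["k"], s["r0"]) for t, s in doc.get("bonds", {}).items()},
            angles={t: (s["k"], s["theta0"])
                    for t, s in doc.get("angles", {}).items()},
            dihedrals={t: tuple(c) for t, c in doc.get("dihedrals", {}).items()},
        )
        return ForceFieldSpec(
            kinds=kinds, pair_table=pairs, bonded=bonded,
            cutoff=doc.get("cutoff", 12.0),
            electrostatics=doc.get("electrostatics", "damped-shifted-force"),
            dsf_alpha=doc.get("dsf_alpha", 0.2),
            rf_dielectric=doc.get("rf_dielectric", 78.5),
            coulomb_constant=doc.get("coulomb_constant", 332.06371),
            half_harmonic=doc.get("half_harmonic", False),
            scale_14=doc.get("scale_14", 0.5),
            lj_shift=doc.get("lj_shift", "energy"),
        )
    except KeyError as exc:
        raise ParseError(f"parameter file missing key {exc}") from None


# ---------------------------------------------------------------------------
# analysis CSV outputs
# ---------------------------------------------------------------------------

def profile_to_frame(profile) -> pd.DataFrame:
    """Density profile as a tidy table: bin_center plus one column/species."""
    data = {"bin_center": profile.centers}
    for s in profile.species:
        data[s] = profile.counts[s]
    return pd.DataFrame(data)


def partition_to_frame(partition) -> pd.DataFrame:
    """Per-frame phase counts as a tidy table."""
    rows = []
    for s, arr in partition.per_frame.items():
        for t in range(arr.shape[0]):
            rows.append({"frame": t, "species": s, "pdms": arr[t, 0],
                         "water": arr[t, 1], "excluded": arr[t, 2]})
    return pd.DataFrame(rows)


def msd_to_frame(times_ps, msd_a2) -> pd.DataFrame:
    return pd.DataFrame({"time_ps": times_ps, "msd_A2": msd_a2})
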