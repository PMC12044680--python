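"""Build a solubility-limited slab system and write it to disk.

Constructs a scaled-down wall | water | PDMS | water | wall box: an
80:20-by-weight mixture of n=1 and n=2 siloxane oligomers in the centre,
SPC water on both sides, and phenol loaded at its aqueous solubility
limit, packed without overlaps and written as extended XYZ plus a LAMMPS
data file.
"""

from collections import Counter

from pdmslab import io
from pdmslab.builder import (
    LoadingPlan,
    SlabSpec,
    build_slab_system,
    organics_at_saturation,
)
from pdmslab.system import Frame, Trajectory

spec = SlabSpec(pdms_width=20.0, water_width=16.0, ly=20.0, lz=20.0)
n_water = 200
n_phenol = organics_at_saturation(1.6, n_water)   # 1.6 mol % at 298.15 K
loading = LoadingPlan(n_water=n_water, n_pdms_n1=3, n_pdms_n2=1,
                      organic="phenol", n_organic=n_phenol,
                      solubility_mol_pct=1.6)

state = build_slab_system(spec, loading, seed=7)
inventory = Counter(m.species for m in state.topology.molecules)

print(f"box:                 {spec.lx:.0f} x {spec.ly:.0f} x {spec.lz:.0f} A")
print(f"phenol at saturation: {n_phenol} molecules "
      f"(floor of {n_water} x 1.6/98.4)")
print(f"inventory:            {dict(inventory)}")
print(f"total sites:          {state.topology.n_sites}")

io.write_lammps_data("slab_system.data", state)
io.write_extxyz("slab_system.extxyz", Trajectory(
    topology=state.topology,
    frames=[Frame(step=0, time=0.0, positions=state.positions,
                  box=state.box)]))
print("wrote slab_system.data and slab_system.extxyz")
print()
print("The walls repel only the polymer, so water and organics may pass;")
print("PDMS is confined to the central 20 A of the non-periodic x axis.")
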