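"""Partition analysis on a synthetic slab trajectory.

Generates a water | PDMS | water trajectory whose phenol occupancies are
prescribed (140 molecules in the polymer slab, 50 in the aqueous
phases), then runs the full analysis chain: 1.5 A density profile,
50%-of-plateau interface detection, 3 A interfacial exclusion, phase
counting, and finally log P and the polymer-phase molar solubility.
"""

from pdmslab import analysis
from pdmslab.synthetic import PartitionScenario, make_partition_trajectory

VOL_PDMS = 28.0 * 40.0 * 40.0        # nominal slab volume, A^3
VOL_WATER = 2.0 * 48.0 * 40.0 * 40.0

scenario = PartitionScenario(
    occupancies={"phenol": (140, 50)},
    n_pdms_markers=2000, n_frames=25, seed=42,
)
trajectory = make_partition_trajectory(scenario)

profile = analysis.density_profile(trajectory, bin_width=1.5)
xl, xr = analysis.locate_interfaces(profile, species="pdms")
partition = analysis.partition_counts(trajectory, (xl, xr), margin=3.0)

counts = partition.counts["phenol"]
lp = partition.log_p("phenol", VOL_PDMS, VOL_WATER)
sol = analysis.molar_solubility(counts["pdms"], VOL_PDMS)

print(f"detected interfaces:      {xl:.1f} .. {xr:.1f} A (true 50 .. 78)")
print(f"phenol in polymer phase:  {counts['pdms']:.0f}")
print(f"phenol in aqueous phase:  {counts['water']:.0f}")
print(f"log P [PDMS/water]:       {lp:.2f}")
print(f"solubility in PDMS phase: {sol:.2f} mol/L")
print()
print("log P near 1 means a ten-fold phenol concentration excess in the")
print("polymer; the solubility is that excess expressed per litre of slab.")
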