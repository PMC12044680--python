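"""Stepwise cooling of a small PDMS box (scaled-down annealing).

Ten n=1 oligomers are equilibrated in the NPT ensemble at 408.15 K and
then cooled to 298.15 K, dwelling a few picoseconds per level.  The cold
polymer ends up denser than the hot one - the thermal expansion that
drives the temperature dependence of sorption.

This is a demonstration at very short dwell times; expect ~2 minutes.
"""

import numpy as np

from pdmslab import md
from pdmslab.builder import assemble_system, pack_nonoverlapping
from pdmslab.parameters import default_forcefield
from pdmslab.templates import pdms_oligomer

ff = default_forcefield()
length = (10 * 236.53 * 1.66054 / 0.85) ** (1 / 3)
box = np.array([length] * 3)
placements = pack_nonoverlapping(
    [(pdms_oligomer(1), 10)], (np.zeros(3) + 0.2, box - 0.2),
    min_dist=2.0, seed=3, box=box, periodic=np.array([True] * 3))
state = md.minimize(assemble_system(placements, box), ff, max_steps=300,
                    f_tol=10.0)

config = md.IntegratorConfig(ensemble="NPT", T_target=408.15, tau_p=500.0,
                             seed=1)
state, _ = md.run_ensemble(state, ff, config, 6000, stride=1000)

schedule = md.AnnealSchedule(T_high=408.15, T_low=298.15, step=110.0,
                             dwell=10_000.0)
state, summaries = md.anneal(state, ff, schedule, config)

for s in summaries:
    print(f"T = {s['T']:6.2f} K   density = {s['mean_density']:.3f} g/cm^3"
          f"   <U> = {s['mean_potential_energy']:8.1f} kcal/mol")
ratio = summaries[-1]["mean_density"] / summaries[0]["mean_density"]
print(f"\ncold/hot density ratio: {ratio:.2f} (> 1: the polymer contracts")
print("on cooling, i.e. heating opens transient free volume for solutes)")
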