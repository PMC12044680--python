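"""Diffusion coefficients from mean-squared displacement.

Generates Brownian trajectories with known diffusivities for two
species, computes the multiple-time-origin MSD and recovers D from the
Einstein relation D = slope/(2n).
"""

from pdmslab import analysis
from pdmslab.synthetic import make_brownian_trajectory

D_TRUE = {"phenol-like": 1.0e-5, "polymer-like": 1.0e-6}  # cm^2/s

trajectory = make_brownian_trajectory(D_TRUE, n_particles=150, dt=1000.0,
                                      n_steps=400, seed=17)

for species, d_true in D_TRUE.items():
    times, msd = analysis.msd(trajectory, species=species)
    est = analysis.diffusion_coefficient(times, msd,
                                         fit_window=(2, len(times) // 2))
    err = abs(est.D_cm2_s - d_true) / d_true * 100
    print(f"{species:13s} D_true = {d_true:.1e}  "
          f"D_fit = {est.D_cm2_s:.2e} cm^2/s  ({err:.1f}% off)")

print()
print("The MSD slope over the well-sampled lags divided by 2n (n = 3")
print("dimensions) recovers each input diffusivity to within a few %.")
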