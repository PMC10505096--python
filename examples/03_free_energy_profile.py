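"""Free-energy profile along z by Boltzmann inversion.

Histograms solute z-positions from a Langevin run over a 3 kT barrier
and inverts P(z) into F(z) = -ln P(z).  The reconstructed barrier height
must agree with the barrier the generator imposed.
"""

import numpy as np

from tbcperm import fes, synth, trajio

spec = synth.SyntheticSpec(
    barrier_height=3.0, n_solutes=64, n_steps=100_000, dt=0.005,
    record_stride=2, seed=42,
)
series = trajio.recentre_and_wrap(synth.simulate_langevin(spec))
profile = fes.compute_fes(series, bin_width=0.1, equilibration_skip=20.0)

print(f"samples binned:        {series.n_frames * series.n_solutes}")
print(f"imposed barrier:       {spec.barrier_height:.2f} kT")
print(f"recovered barrier:     {profile.barrier_height():.2f} kT")
kj = profile.barrier_height() * 0.008314462618153239 * spec.temperature
print(f"                     = {kj:.1f} kJ/mol at {spec.temperature:.0f} K")

print("\nprofile around the membrane (every 5th bin):")
print("  z/nm    F/kT")
for z, f, ok in zip(
    profile.bin_centers[::5], profile.free_energy[::5], profile.sampled[::5]
):
    print(f"  {z:+5.2f}   {f:5.2f}" if ok else f"  {z:+5.2f}   (unsampled)")
print(
    "\nF is flat in the bulk, rises through the membrane region and peaks "
    "at the\nmidplane: Boltzmann inversion recovers the generator's potential."
)
assert np.isfinite(profile.barrier_height())
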