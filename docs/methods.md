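# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations behind `tbcperm`. It documents how the
package computes; every number quoted here is produced by the test
suite or the examples, not asserted from memory.

## Event definition and the counting state machine

A translocation event is a trajectory segment that starts in bulk
solvent on one side of the bilayer and first reaches a plane a fixed
offset (default 1.0 nm) beyond the opposite leaflet surface. Two
reference surfaces are needed: the leaflet boundaries, taken as the
per-leaflet mean headgroup z (time-averaged), and the crossing planes at
boundary ± offset. The offset is measured from the leaflet surface, not
the midplane: the plane lies "beyond the bilayer", and the headgroup
surfaces are the bilayer's edges.

The detector is a per-solute three-region state machine with
hysteresis:

* a solute's bulk assignment changes only on full arrival in the
  opposite bulk region; entering the membrane region and retreating
  never changes the assignment, so boundary recrossings cannot be
  double-counted;
* solutes that begin inside the membrane region are unassigned until
  they first reach a bulk region;
* arrival exactly on a crossing plane counts as arrival (closed far
  boundary), and events are timestamped at first arrival;
* frame pairs whose displacement exceeds half the box length are
  periodic-image jumps: they transfer the bulk assignment silently,
  because travelling around the periodic boundary is not membrane
  passage. A flip whose connecting frames contain any jump is therefore
  never an event. (A path that both wraps and crosses the membrane
  between two recorded frames would be misclassified; at any realistic
  output stride such a double move is impossible.)

The detector requires recentred coordinates (membrane midplane at
z ≈ 0) and refuses geometries whose crossing planes fall outside the
box, since no bulk region would exist. It is checked against an
independent frame-by-frame scanner on hundreds of randomized
trajectories, and against crafted piecewise-linear paths whose event
count is known symbolically. Counting is time-reversal symmetric (up
and down events exchange) and never loses events as the output stride
is refined.

## Steady-state rate and its uncertainty

The running rate k(t) = (cumulative events)/t is evaluated at regular
checkpoints (default 10 ns). Steady state is declared from the earliest
checkpoint after which every finite-difference derivative satisfies
|dk/dt| < 0.004 (k in ns⁻¹, spacing in ns, so the threshold carries
units ns⁻²; the bare number matches the published criterion). The
reported k_ss is the average of k over the plateau; at least 5 plateau
checkpoints are required (guards against single-interval false
plateaus), otherwise a non-convergence error reports the last |dk/dt| —
the signal that the trajectory is too short for that solute.

Uncertainty: the plateau average correlates the values N(t_i)/t_i, so
the package reports the exact Poisson counting error of that estimator,

    var(k_ss) = (k_ss / m²) · Σ_ij 1 / max(t_i, t_j),

which reduces to the familiar √n/T when the plateau is a single
checkpoint and is never tighter than it. The simpler three-block
standard error is available as `sigma_method="block"`. On synthetic
Poisson streams the 2σ interval covers the true rate in ≈94% of seeded
replicates.

## Permeability conversion

P_sim = r/(2AC) with r = k_ss/N_A in mol/s, A the lateral
cross-sectional area in cm² and C the concentration in mol/cm³; the
factor 2 reflects the bidirectional equilibrium flux. Defaults are
A = 25 nm² (the standard 96-lipid bilayer patch) and C from the
trajectory's own solute count in the box volume A·L_z. These defaults
are explicit, overridable inputs: the geometric factors actually used
to produce the packaged per-compound P_sim values are not fully
recoverable from the published record, so the packaged table is treated
as data rather than as a conversion target (re-deriving it from the
packaged k with the naive defaults gives values about 4× larger).
P_app = P_sim/2 converts a single-bilayer permeability to the
transwell-comparable two-membrane quantity.

## Free-energy profiles

F(z) = −ln P(z) in kT, from a histogram of all solute copies over the
box (default bin width 0.1 nm, equilibration skip in ns). Empty bins
are reported as unsampled (NaN plus mask), never as numbers; the gauge
fixes min F = 0 over sampled bins. Optional mirror symmetrization about
z = 0 is off by default (the model membrane is compositionally
symmetric, but symmetrization is a variance-reduction choice, not part
of the estimator). Conversion to kJ/mol uses the series' own
temperature. Against exact i.i.d. Boltzmann samples of a 3 kT Gaussian
barrier the reconstruction is accurate to < 0.1 kT at 10⁶ samples; from
Langevin dynamics the imposed barrier is recovered within 0.3 kT.

## Calibration

Ordinary least squares of log₁₀ P_app on log₁₀ P_sim
(`scipy.stats.linregress`; R² is the squared Pearson correlation, the
p-value the two-sided slope t-test on n−2 df). Log base 10 throughout.
The packaged 18-compound library yields (m, c, R²) = (1.126, −4.818,
0.587) at 167 °C; the 13 compounds that also converged at 127 °C give
(1.177, −3.735, 0.542) there, and (1.728, −5.198, 0.679) when refitted
at 167 °C on the same subset.

Frozen lines ship in two precisions because the published worked
examples rounded differently: (1.124, −4.819) reproduces the
training-prediction rows, while the rounded (1.12, −4.82) reproduces
the reference-table prediction column; (1.17, −3.73) is the 127 °C
line. (The published 127 °C table header prints different coefficients,
(1.277, −3.65), but its own rows and the regression figure are
consistent with (1.17, −3.73), which this package adopts.) Two
experimental nicotine values circulate (1.73 vs 1.78 ×10⁻⁴ cm/s); both
are stored with provenance, and the worked-example variant is used when
reproducing those rows.

Prediction is 10^(m·log₁₀P_sim + c); accuracy is scored as the
order-of-magnitude error |log₁₀P_exp − log₁₀P_pred|. The trimmed mean
(drop errors above two decades) reproduces the published 127 °C average
0.4646; the published 167 °C average (0.55040) does not equal the mean
of its own per-row errors (0.600) under any single-row exclusion, so
the row-wise mean is the quantity this package reproduces and the
printed average is retained as provenance only.

Subset stability fits every n-compound subset of the library
exhaustively (816 / 18 564 / 48 620 / 18 564 / 816 subsets for
n = 3…15; vectorized normal equations make the full sweep take well
under a second) and records the slope mean ± SD per n. Random seeded
subsampling is available beyond the default 10⁵-subset cap. Because
every fitted slope is positive, ranking by P_sim is identical to
ranking by predicted P_app; this order-isomorphism is asserted in the
tests.

## Synthetic generator and its oracles

The generator integrates overdamped (Smoluchowski) Langevin dynamics,
z ← z − D U′(z) dt + √(2 D dt)·η, with U(z) = ΔG·exp(−z²/2w²) in kT,
periodic over the box. Defaults mirror the study conditions the real
pipeline targets: a 12 nm box, 20 solute copies, 167 °C; the synthetic
leaflet surfaces sit at ±2w. One-dimensional dynamics suffice because
the method reads only z, and they admit exact oracles:

* the equilibrium crossing rate, from the 1-D reactive-flux /
  mean-first-passage integrals k = 2 n_solutes/(Z·R) with
  R = ∫e^{U}/D dz across the membrane channel and Z = ∫e^{−U} dz over
  the box (quadrature; for ΔG = 0 it reduces to the free-diffusion
  closed form D/(cL) per solute);
* exact i.i.d. Boltzmann position samples by rejection sampling
  (acceptance probability e^{−U} exactly, since U ≥ 0);
* crafted piecewise-linear paths with symbolic event counts;
* synthetic compound libraries with prescribed (m₀, c₀, σ) in log-log
  space, P_sim log-uniform over the two-plus decades the real library
  spans.

A construction-time stability check rejects time steps whose peak
deterministic drift exceeds w/4. Euler–Maruyama discretization biases
the crossing rate low by O(dt); at dt = 0.0025 ns (D = 5 nm²/ns,
w = 1 nm) the residual bias is ≲1%, well inside the 3σ counting bands
used in the tests. Oracle-agreement tests run 64 solutes for 1–1.5 μs
of synthetic time at barrier heights of 2–4 kT (chosen to span the
fast-to-slow crossing regimes while keeping hundreds-to-thousands of
events per run); recording every fourth step leaves the counts
unchanged because a double transit between recorded frames is
impossible at that stride.

What the generator does **not** emulate: explicit lipids and their
fluctuating surfaces, solute conformational degrees of freedom,
anisotropic and position-dependent diffusion, finite-size pressure
coupling. Passing tests therefore certify the counting, plateau,
inversion and calibration machinery — not the fidelity of any MD force
field. Conversely, the packaged library values come from the original
multi-microsecond MD record and are desk-reproducible only down to the
calibration stage, which is why the raw-rate claims are validated
against synthetic oracles instead.

## Trajectory input and units

Internal units are fixed: ns, nm, K. The interchange format is a plain
text dialect ('#' headers for label, temperature, box length, leaflet
reference and ground-truth metadata; whitespace-separated time and
per-solute z columns) that round-trips bit-identically at full
precision. Standard MD containers (XTC/TRR/DCD + PDB/GRO) are read
through an optional MDAnalysis adapter — solute position is the
per-residue centre of mass of the selected atoms (robust to internal
conformational motion; which atoms define "position" is a modelling
choice, not part of the event definition), leaflets are split by sign
of z about the lipids' mean, Å and ps are converted at the boundary.
The core package never requires binary-format libraries, and no binary
trajectory writing is provided.

## Known limitations

* The high-temperature trick presumes the solute and membrane survive
  the temperature in simulation; the calibration transfers only to
  compounds inside the library's permeability range (about 10⁻⁷–10⁻³
  cm/s experimentally).
* The calibration carries no uncertainty propagation from k_sigma into
  prediction intervals, and no joint multi-temperature fit; it is a
  ranking tool with ~1-decade accuracy, not an absolute predictor.
* Arrhenius extrapolation and solubility–diffusion (ISD) permeability
  estimates are out of scope; the packaged Arrhenius column is
  provenance data only.
* The validation-set predictions (sertraline, Risperdal, diazepam,
  lacosamide) are stored as fixtures: their simulation inputs are not
  redistributable, so they cannot be recomputed here.
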