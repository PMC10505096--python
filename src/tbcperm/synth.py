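"""Synthetic trajectories and compound libraries with known ground truth.

Real inputs to the pipeline are multi-microsecond MD trajectories that
cannot be regenerated at a desk, so every stage is validated against
synthetic data whose correct answer is known:

* :func:`simulate_langevin` — overdamped (Smoluchowski) 1-D Langevin
  dynamics of point solutes in a periodic box with a Gaussian free-energy
  barrier standing in for the bilayer.  Only the membrane-normal
  coordinate matters to the counting method, and 1-D dynamics admit exact
  rate and distribution oracles.
* :func:`analytic_crossing_rate` — the exact equilibrium transition rate
  for that system, from the 1-D reactive-flux (mean-first-passage)
  integrals evaluated by quadrature.
* :func:`crafted_trajectory` — piecewise-linear paths whose event count
  is known by construction (transits, aborted entries, periodic jumps).
* :func:`boltzmann_positions` — i.i.d. samples from the barrier's exact
  Boltzmann distribution, for testing free-energy reconstruction.
* :func:`synthetic_library` — compound libraries with a prescribed
  log-log slope, intercept and scatter, for calibration recovery tests.

Default geometry mirrors the study conditions the real pipeline targets:
a ~12 nm box with 20 solute copies; the bilayer "edges" are placed at
z = +-2w for a Gaussian barrier of half-width w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .calib import CompoundRecord
from .errors import StabilityError
from .trajio import ZSeries

__all__ = [
    "SyntheticSpec",
    "simulate_langevin",
    "analytic_crossing_rate",
    "crafted_trajectory",
    "boltzmann_positions",
    "boltzmann_zseries",
    "synthetic_library",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the 1-D Langevin membrane-crossing system.

    The potential is a Gaussian barrier U(z) = dG exp(-z^2 / 2 w^2) in kT
    units, periodic over the box; ``barrier_height`` is dG, and the
    membrane edges (the stand-in for leaflet surfaces) sit at +-2w.
    """

    barrier_height: float = 3.0      # kT
    barrier_halfwidth: float = 1.0   # nm
    diffusion_D: float = 5.0         # nm^2/ns
    box_z: float = 12.0              # nm
    n_solutes: int = 20
    dt: float = 0.005                # ns
    n_steps: int = 100_000
    temperature: float = 440.15      # K (167 degC, the main study condition)
    seed: int = 0
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be >= 0")
        for name in ("barrier_halfwidth", "diffusion_D", "box_z", "dt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_solutes < 1 or self.n_steps < 1 or self.record_stride < 1:
            raise ValueError("n_solutes, n_steps and record_stride must be >= 1")
        if self.membrane_edge * 2 >= self.box_z:
            raise ValueError("barrier wider than the box")
        # deterministic drift per step must stay well below the barrier
        # width, or Euler integration distorts the crossing dynamics
        w = self.barrier_halfwidth
        max_force = self.barrier_height * np.exp(-0.5) / w  # kT/nm
        drift = self.diffusion_D * max_force * self.dt
        if drift > 0.25 * w:
            raise StabilityError(
                f"dt = {self.dt} ns gives a peak drift of {drift:.3f} nm per "
                f"step (> w/4 = {0.25 * w:.3f} nm); reduce dt"
            )

    @property
    def membrane_edge(self) -> float:
        """z of the synthetic leaflet surface: two barrier half-widths."""
        return 2.0 * self.barrier_halfwidth

    def potential(self, z: np.ndarray | float) -> np.ndarray | float:
        w = self.barrier_halfwidth
        return self.barrier_height * np.exp(-np.square(z) / (2.0 * w * w))

    def force(self, z: np.ndarray | float) -> np.ndarray | float:
        """-dU/dz in kT/nm."""
        w = self.barrier_halfwidth
        return self.barrier_height * z / (w * w) * np.exp(-np.square(z) / (2.0 * w * w))


def simulate_langevin(spec: SyntheticSpec) -> ZSeries:
    """Integrate overdamped Langevin dynamics; deterministic given seed.

    Update rule (Euler-Maruyama, potential in kT so beta is absorbed):

        z <- z - D U'(z) dt + sqrt(2 D dt) eta,   eta ~ N(0, 1)

    wrapped into the periodic box each step.  Solutes start uniformly in
    the bulk region (|z| > membrane edge).  Returns a ZSeries whose
    ``lipid_ref_z`` is the constant +-(membrane edge) and whose ``meta``
    records the ground-truth parameters.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.box_z
    half = L / 2.0
    edge = spec.membrane_edge

    z = rng.uniform(edge, half, size=spec.n_solutes)
    z *= rng.choice((-1.0, 1.0), size=spec.n_solutes)

    n_rec = spec.n_steps // spec.record_stride + 1
    out = np.empty((n_rec, spec.n_solutes))
    out[0] = z
    rec = 1
    sqrt_noise = np.sqrt(2.0 * spec.diffusion_D * spec.dt)
    drift_scale = spec.diffusion_D * spec.dt
    chunk = 4096
    step = 0
    while step < spec.n_steps:
        todo = min(chunk, spec.n_steps - step)
        noise = rng.standard_normal((todo, spec.n_solutes))
        for i in range(todo):
            z = z + drift_scale * spec.force(z) + sqrt_noise * noise[i]
            z = (z + half) % L - half
            step += 1
            if step % spec.record_stride == 0:
                out[rec] = z
                rec += 1
    times = spec.dt * spec.record_stride * np.arange(n_rec)
    return ZSeries(
        times=times,
        z=out[:rec],
        box_z=L,
        temperature=spec.temperature,
        lipid_ref_z=np.array([-edge, edge]),
        label="langevin",
        meta={
            "generator": "overdamped-langevin",
            "barrier_height_kT": spec.barrier_height,
            "barrier_halfwidth_nm": spec.barrier_halfwidth,
            "diffusion_D_nm2_ns": spec.diffusion_D,
            "seed": spec.seed,
        },
    )


def analytic_crossing_rate(spec: SyntheticSpec, crossing_offset: float = 1.0) -> float:
    """Exact steady-state crossing rate of the synthetic system (ns^-1).

    For 1-D overdamped diffusion at equilibrium, the frequency of
    reactive transitions between the two crossing planes at z = -+c
    (c = membrane edge + offset) follows from the mean-first-passage /
    reactive-flux integrals:

        nu(one direction) = 1 / (Z R),
        R = int_{-c}^{+c} e^{U(z)} / D dz,     Z = int_box e^{-U(z)} dz.

    The detector counts both directions, and every solute contributes, so

        k = n_solutes * 2 / (Z R).

    For U = 0 this reduces to the free-diffusion first-passage form
    k = n_solutes * D / (c L).
    """
    if not crossing_offset > 0:
        raise ValueError("crossing_offset must be positive")
    c = spec.membrane_edge + crossing_offset
    half = spec.box_z / 2.0
    if c >= half:
        raise ValueError("crossing planes fall outside the box")
    resistance, err_r = integrate.quad(
        lambda z: np.exp(spec.potential(z)) / spec.diffusion_D, -c, c, limit=200
    )
    partition, err_z = integrate.quad(
        lambda z: np.exp(-spec.potential(z)), -half, half, limit=200
    )
    if err_r > 1e-6 * resistance or err_z > 1e-6 * partition:
        raise ArithmeticError("quadrature for the crossing rate did not converge")
    return spec.n_solutes * 2.0 / (partition * resistance)


def crafted_trajectory(
    waypoints: list[tuple[float, float]],
    box_z: float = 12.0,
    membrane_edge: float = 2.0,
    crossing_offset: float = 1.0,
    dt: float = 0.1,
    temperature: float = 300.0,
) -> ZSeries:
    """Piecewise-linear single-solute path with a known event count.

    Consecutive waypoints whose separation exceeds half the box encode a
    periodic-image jump (the path holds the old position, then steps);
    all other segments are linearly interpolated.  Sample times are the
    regular dt grid united with the waypoint times, so no waypoint
    extremum is ever missed at any resolution.

    The ground-truth translocation count, derived symbolically from the
    waypoint region sequence, is stored in ``meta['true_events']``.
    """
    if len(waypoints) < 2:
        raise ValueError("need at least two waypoints")
    t_wp = np.asarray([w[0] for w in waypoints], dtype=float)
    z_wp = np.asarray([w[1] for w in waypoints], dtype=float)
    if not np.all(np.diff(t_wp) > 0):
        raise ValueError("waypoints must be strictly time-ordered")
    jump_seg = np.abs(np.diff(z_wp)) > box_z / 2.0

    grid = np.arange(t_wp[0], t_wp[-1] + dt / 2.0, dt)
    times = np.unique(np.concatenate([grid, t_wp]))
    seg = np.clip(np.searchsorted(t_wp, times, side="right") - 1, 0, len(t_wp) - 2)
    t0, t1 = t_wp[seg], t_wp[seg + 1]
    z0, z1 = z_wp[seg], z_wp[seg + 1]
    frac = np.where(t1 > t0, (times - t0) / (t1 - t0), 0.0)
    z = z0 + frac * (z1 - z0)
    # jump segments hold the old side until the far endpoint
    is_jump = jump_seg[seg]
    z[is_jump] = np.where(frac[is_jump] >= 1.0, z1[is_jump], z0[is_jump])

    true_events = _waypoint_event_count(
        z_wp, jump_seg, membrane_edge + crossing_offset
    )
    return ZSeries(
        times=times,
        z=z[:, None],
        box_z=box_z,
        temperature=temperature,
        lipid_ref_z=np.array([-membrane_edge, membrane_edge]),
        label="crafted",
        meta={"true_events": true_events},
    )


def _waypoint_event_count(
    z_wp: np.ndarray, jump_seg: np.ndarray, plane: float
) -> int:
    """Symbolic event count from the waypoint region sequence."""
    regions = np.zeros(len(z_wp), dtype=int)
    regions[z_wp <= -plane] = -1
    regions[z_wp >= plane] = 1
    jumps_before = np.concatenate([[0], np.cumsum(jump_seg)])
    count = 0
    state = 0
    state_jumps = 0
    for i, r in enumerate(regions):
        if r == 0:
            continue
        if state != 0 and r != state and jumps_before[i] == state_jumps:
            count += 1
        state = r
        state_jumps = jumps_before[i]
    return count


def boltzmann_positions(
    spec: SyntheticSpec, n_samples: int, seed: int | None = None
) -> np.ndarray:
    """i.i.d. z samples from the exact Boltzmann density e^{-U(z)} / Z.

    Rejection sampling with a uniform envelope over the box; since
    U >= 0, the acceptance probability is exactly e^{-U}.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    half = spec.box_z / 2.0
    out = np.empty(n_samples)
    filled = 0
    while filled < n_samples:
        m = max(1024, int(1.5 * (n_samples - filled)))
        cand = rng.uniform(-half, half, size=m)
        accept = rng.uniform(size=m) < np.exp(-spec.potential(cand))
        got = cand[accept][: n_samples - filled]
        out[filled : filled + got.size] = got
        filled += got.size
    return out


def boltzmann_zseries(
    spec: SyntheticSpec, n_samples: int, seed: int | None = None
) -> ZSeries:
    """Boltzmann samples packaged as a one-solute ZSeries for binning."""
    z = boltzmann_positions(spec, n_samples, seed=seed)
    return ZSeries(
        times=np.arange(n_samples, dtype=float),
        z=z[:, None],
        box_z=spec.box_z,
        temperature=spec.temperature,
        lipid_ref_z=np.array([-spec.membrane_edge, spec.membrane_edge]),
        label="boltzmann-sample",
        meta={"barrier_height_kT": spec.barrier_height},
    )


def synthetic_library(
    m0: float,
    c0: float,
    noise_sigma: float,
    n_compounds: int = 18,
    seed: int | None = None,
    p_sim_range: tuple[float, float] = (7e-2, 1.7e1),
    temperature_label: str = "167C",
) -> list[CompoundRecord]:
    """Compound library with a prescribed log-log structure.

    P_sim is log-uniform over *p_sim_range* (defaults span the two-plus
    decades the high-temperature library covers) and

        log10 P_app = m0 log10 P_sim + c0 + N(0, noise_sigma).
    """
    if n_compounds < 3:
        raise ValueError("n_compounds must be >= 3")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(p_sim_range[0]), np.log10(p_sim_range[1])
    log_psim = rng.uniform(lo, hi, size=n_compounds)
    log_papp = m0 * log_psim + c0
    if noise_sigma > 0:
        log_papp = log_papp + rng.normal(0.0, noise_sigma, size=n_compounds)
    return [
        CompoundRecord(
            name=f"cmpd-{i + 1:02d}",
            index=i + 1,
            p_sim={temperature_label: float(10.0**lx)},
            p_app_exp=float(10.0**ly),
            reference="synthetic",
        )
        for i, (lx, ly) in enumerate(zip(log_psim, log_papp))
    ]
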