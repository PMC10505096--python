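"""Steady-state crossing rate and its conversion to permeability.

The running rate k(t) from :mod:`tbcperm.tbc` converges to a plateau once
enough crossings have accumulated.  Steady state is declared by the
derivative criterion |dk/dt| < threshold (default 0.004 ns^-2 with k in
ns^-1 and checkpoints in ns), and the steady-state rate is the average of
k over the plateau.

The rate converts to a single-bilayer permeability by

    P_sim = r / (2 A C),        r = k / N_A  (mol/s)

with A the lateral cross-sectional area of the membrane and C the solute
concentration; the factor 2 accounts for the bidirectional flux.  The
transwell-comparable apparent permeability across one cell (two
membranes) is P_app = P_sim / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NonConvergenceError
from .tbc import RateSeries

__all__ = [
    "N_A",
    "K_B_KJ_MOL",
    "SteadyState",
    "PermeabilityEstimate",
    "steady_state_rate",
    "permeability_from_rate",
    "apparent_permeability",
    "molar_concentration",
    "permeability_estimate",
]

#: Avogadro constant, mol^-1 (exact, SI 2019)
N_A = 6.02214076e23
#: Boltzmann constant expressed per mole, kJ/(mol K) (exact, SI 2019)
K_B_KJ_MOL = 0.008314462618153239

#: nm^2 -> cm^2
_NM2_TO_CM2 = 1e-14
#: nm^3 -> cm^3
_NM3_TO_CM3 = 1e-21


@dataclass(frozen=True)
class SteadyState:
    """Plateau rate with its counting uncertainty."""

    k_ss: float            # ns^-1
    k_sigma: float         # ns^-1, +-1 sigma
    plateau_onset: float   # ns, first checkpoint of the plateau
    n_plateau_events: int  # crossings inside the plateau window


@dataclass(frozen=True)
class PermeabilityEstimate:
    """Steady-state rate and the permeability it implies.

    ``P_sigma / P_sim`` equals ``k_sigma / k_ss`` — the geometric factors
    are treated as exact, so the relative counting error propagates
    unchanged.
    """

    k_ss: float                # ns^-1
    k_sigma: float             # ns^-1
    area_A: float              # nm^2
    concentration_C: float     # mol/cm^3
    P_sim: float               # cm/s
    P_sigma: float             # cm/s
    temperature: float         # K
    molar_rate_r: float        # mol/s
    plateau_onset: float       # ns

    @property
    def P_app(self) -> float:
        return apparent_permeability(self.P_sim)


def steady_state_rate(
    rates: RateSeries,
    threshold: float = 0.004,
    min_plateau_checkpoints: int = 5,
    sigma_method: str = "poisson",
) -> SteadyState:
    """Locate the k(t) plateau and average over it.

    The plateau onset is the earliest checkpoint from which |dk/dt| stays
    below *threshold* for every remaining interval; at least
    *min_plateau_checkpoints* checkpoints must lie in the plateau, else
    the trajectory is declared unconverged (too short for this solute).

    ``sigma_method='poisson'`` (default) reports the exact Poisson
    counting error of the plateau-averaged estimator: since k_ss averages
    the correlated values N(t_i)/t_i, its variance is

        var(k_ss) = (k / m^2) * sum_ij 1 / max(t_i, t_j)

    which collapses to the familiar sqrt(n)/T for a single checkpoint.
    ``'block'`` instead takes the standard error of k averaged over three
    equal blocks of the plateau.
    """
    if min_plateau_checkpoints < 1:
        raise ValueError("min_plateau_checkpoints must be >= 1")
    n = rates.n_checkpoints
    if n < min_plateau_checkpoints + 1:
        raise NonConvergenceError(
            f"only {n} checkpoints; need at least {min_plateau_checkpoints + 1}"
        )
    bad = np.abs(rates.dk_dt) >= threshold
    # first checkpoint index j such that every interval at or after j is quiet
    last_bad = int(np.nonzero(bad)[0][-1]) if bad.any() else -1
    onset_idx = last_bad + 1
    n_plateau = n - onset_idx
    if n_plateau < min_plateau_checkpoints:
        raise NonConvergenceError(
            f"plateau of {n_plateau} checkpoints shorter than the required "
            f"{min_plateau_checkpoints}; trajectory too short",
            last_dk_dt=float(rates.dk_dt[-1]) if rates.dk_dt.size else None,
        )
    k_plateau = rates.k[onset_idx:]
    k_ss = float(k_plateau.mean())
    t = rates.checkpoint_times
    events_before = int(rates.cumulative_events[onset_idx - 1]) if onset_idx > 0 else 0
    n_events = int(rates.cumulative_events[-1]) - events_before
    if sigma_method == "poisson":
        t_pl = t[onset_idx:]
        m = len(t_pl)
        # pairwise 1/max(t_i, t_j) over the ascending checkpoint times:
        # the pair count whose max is t_i is (2 i + 1)
        pair_sum = float(np.sum((2 * np.arange(m) + 1) / t_pl))
        k_sigma = float(np.sqrt(max(k_ss, 0.0) * pair_sum) / m)
    elif sigma_method == "block":
        blocks = np.array_split(k_plateau, 3)
        means = np.array([b.mean() for b in blocks if b.size])
        k_sigma = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else 0.0
    else:
        raise ValueError(f"unknown sigma_method: {sigma_method!r}")
    return SteadyState(
        k_ss=k_ss,
        k_sigma=k_sigma,
        plateau_onset=float(t[onset_idx]),
        n_plateau_events=n_events,
    )


def permeability_from_rate(
    k_ss: float,
    area_A: float,
    concentration_C: float,
) -> float:
    """Convert a crossing rate to a single-bilayer permeability.

    Parameters
    ----------
    k_ss : steady-state crossing frequency, ns^-1.
    area_A : lateral cross-sectional membrane area, nm^2.
    concentration_C : solute concentration, mol/cm^3.

    Returns
    -------
    P_sim in cm/s:  (k 1e9 / N_A) / (2 * A[cm^2] * C).
    """
    if k_ss < 0:
        raise ValueError("k_ss must be non-negative")
    if not area_A > 0:
        raise ValueError("area_A must be positive")
    if not concentration_C > 0:
        raise ValueError("concentration_C must be positive")
    r = k_ss * 1e9 / N_A  # mol/s
    return r / (2.0 * area_A * _NM2_TO_CM2 * concentration_C)


def apparent_permeability(P_sim: float) -> float:
    """Transwell-comparable permeability across two membranes: P_sim / 2."""
    if P_sim < 0:
        raise ValueError("P_sim must be non-negative")
    return P_sim / 2.0


def molar_concentration(n_solutes: int, volume_nm3: float) -> float:
    """Concentration (mol/cm^3) of n copies in a box volume given in nm^3."""
    if n_solutes < 1:
        raise ValueError("need at least one solute copy")
    if not volume_nm3 > 0:
        raise ValueError("volume must be positive")
    return n_solutes / (N_A * volume_nm3 * _NM3_TO_CM3)


def permeability_estimate(
    rates: RateSeries,
    area_A: float,
    concentration_C: float,
    temperature: float,
    threshold: float = 0.004,
    min_plateau_checkpoints: int = 5,
    sigma_method: str = "poisson",
) -> PermeabilityEstimate:
    """Steady-state detection and unit conversion in one call."""
    ss = steady_state_rate(
        rates,
        threshold=threshold,
        min_plateau_checkpoints=min_plateau_checkpoints,
        sigma_method=sigma_method,
    )
    P_sim = permeability_from_rate(ss.k_ss, area_A, concentration_C)
    rel = ss.k_sigma / ss.k_ss if ss.k_ss > 0 else 0.0
    return PermeabilityEstimate(
        k_ss=ss.k_ss,
        k_sigma=ss.k_sigma,
        area_A=area_A,
        concentration_C=concentration_C,
        P_sim=P_sim,
        P_sigma=P_sim * rel,
        temperature=temperature,
        molar_rate_r=ss.k_ss * 1e9 / N_A,
        plateau_onset=ss.plateau_onset,
    )
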