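"""One-dimensional free-energy surface along the membrane normal.

At equilibrium the z-positions of a solute sample the Boltzmann
distribution, so binning them into P(z) and inverting

    F(z) = -ln P(z)   (kT units)

recovers the free-energy profile across the bilayer.  The gauge is fixed
by shifting the minimum over sampled bins to zero; bins that were never
visited carry no number at all (an "unsampled" mask), because Boltzmann
inversion is undefined there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyDataError
from .kinetics import K_B_KJ_MOL
from .trajio import ZSeries

__all__ = ["FESProfile", "compute_fes"]


@dataclass(frozen=True)
class FESProfile:
    """Binned probability density and free energy along z.

    ``free_energy`` is in kT at ``temperature``; entries where
    ``sampled`` is False are NaN placeholders, not values.
    """

    bin_centers: np.ndarray   # nm
    probability: np.ndarray   # density, integrates to 1 over sampled bins
    free_energy: np.ndarray   # kT, min over sampled bins = 0
    sampled: np.ndarray       # bool mask
    temperature: float        # K
    bin_width: float          # nm

    @property
    def free_energy_kj_mol(self) -> np.ndarray:
        """Profile in kJ/mol at the series' own simulation temperature."""
        return self.free_energy * K_B_KJ_MOL * self.temperature

    def barrier_height(self) -> float:
        """Max free energy over sampled bins (kT); crude barrier readout."""
        return float(np.nanmax(self.free_energy))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_nm": self.bin_centers,
                "P": self.probability,
                "F_kT": self.free_energy,
                "sampled": self.sampled,
            }
        )


def compute_fes(
    series: ZSeries,
    bin_width: float = 0.1,
    equilibration_skip: float = 0.0,
    symmetrize: bool = False,
) -> FESProfile:
    """Boltzmann-invert the z histogram of all solute copies.

    Parameters
    ----------
    bin_width : nm; the box is divided into round(box_z / bin_width) equal
        bins spanning [-box_z/2, +box_z/2].
    equilibration_skip : ns; frames earlier than this (relative to the
        first frame) are discarded before binning.
    symmetrize : average the histogram with its mirror image about z = 0
        before inversion.  The membrane model is compositionally
        symmetric, so this is a legitimate variance reduction, but it is
        off by default.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    t0 = series.times[0]
    keep = series.times - t0 >= equilibration_skip
    if not keep.any():
        raise EmptyDataError("equilibration_skip discards every frame")
    box = series.constant_box_z()
    n_bins = max(1, int(round(box / bin_width)))
    edges = np.linspace(-box / 2.0, box / 2.0, n_bins + 1)
    counts, _ = np.histogram(series.z[keep].ravel(), bins=edges)
    counts = counts.astype(float)
    if symmetrize:
        counts = 0.5 * (counts + counts[::-1])
    width = edges[1] - edges[0]
    total = counts.sum()
    prob = counts / (total * width)
    sampled = counts > 0
    free = np.full(n_bins, np.nan)
    free[sampled] = -np.log(prob[sampled])
    free -= np.nanmin(free)
    return FESProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        probability=prob,
        free_energy=free,
        sampled=sampled,
        temperature=series.temperature,
        bin_width=float(width),
    )
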