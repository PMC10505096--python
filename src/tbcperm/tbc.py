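"""Transition-based counting of complete transbilayer crossings.

A translocation event is a trajectory segment that starts in bulk solvent
on one side of the bilayer, passes through the membrane, and first reaches
a plane a fixed offset (default 1.0 nm) beyond the opposite leaflet
surface.  Counting such events per unit time gives the crossing frequency
k(t); its steady-state plateau is the quantity converted to permeability
in :mod:`tbcperm.kinetics`.

The detector is a per-solute three-region state machine with hysteresis:

* regions: ``bulk_below`` (z at or below the lower crossing plane),
  ``membrane-adjacent`` (between the planes), ``bulk_above`` (z at or
  beyond the upper plane).  Arrival exactly on a plane counts as arrived.
* a solute's bulk assignment changes only when it fully reaches the
  opposite bulk region; grazing the membrane region and returning never
  produces an event (no double counting of surface recrossings);
* solutes that start inside the membrane region are unassigned until they
  first reach a bulk region;
* frame pairs flagged as periodic-image jumps transfer the assignment
  silently: moving between the bulk regions around the periodic boundary
  is not membrane passage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, DegenerateMembraneError
from .trajio import ZSeries

__all__ = [
    "MembraneGeometry",
    "CrossingEvent",
    "RateSeries",
    "estimate_membrane_geometry",
    "detect_crossings",
    "rate_series",
    "events_table",
]

#: minimum leaflet separation (nm) below which the membrane is rejected
_MIN_LEAFLET_SEPARATION = 1.0


@dataclass(frozen=True)
class MembraneGeometry:
    """Leaflet surfaces and the crossing-plane offset, in recentred nm.

    ``lower_boundary``/``upper_boundary`` are the leaflet headgroup
    surfaces; the crossing planes sit ``crossing_offset`` nm beyond them,
    i.e. the event-defining plane is measured from the bilayer's edge,
    not from its midplane.
    """

    lower_boundary: float
    upper_boundary: float
    crossing_offset: float = 1.0

    def __post_init__(self) -> None:
        if not self.crossing_offset > 0:
            raise GeometryError("crossing_offset must be positive")
        if not self.lower_boundary < self.upper_boundary:
            raise GeometryError("lower_boundary must lie below upper_boundary")

    @property
    def lower_plane(self) -> float:
        return self.lower_boundary - self.crossing_offset

    @property
    def upper_plane(self) -> float:
        return self.upper_boundary + self.crossing_offset

    @property
    def midplane(self) -> float:
        return 0.5 * (self.lower_boundary + self.upper_boundary)

    @property
    def thickness(self) -> float:
        return self.upper_boundary - self.lower_boundary


@dataclass(frozen=True)
class CrossingEvent:
    """One complete translocation.

    ``start_time`` is the last time the solute was seen in the source bulk
    before entering the membrane; ``end_time`` the first time it was seen
    at or beyond the far crossing plane.
    """

    solute_index: int
    start_time: float
    end_time: float
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValueError("event end_time must exceed start_time")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass(frozen=True)
class RateSeries:
    """Running crossing-rate estimate at regular checkpoints.

    ``k[i]`` is exactly ``cumulative_events[i] / checkpoint_times[i]``
    (ns^-1); ``dk_dt[i]`` is the finite difference of k over the interval
    (checkpoint_times[i], checkpoint_times[i+1]) in ns^-2.
    """

    checkpoint_times: np.ndarray
    cumulative_events: np.ndarray
    k: np.ndarray
    dk_dt: np.ndarray

    @property
    def n_checkpoints(self) -> int:
        return len(self.checkpoint_times)


def estimate_membrane_geometry(
    series: ZSeries,
    mode: str = "static",
    crossing_offset: float = 1.0,
) -> MembraneGeometry:
    """Locate the leaflet surfaces from the lipid headgroup reference.

    In ``static`` mode (the default, and the only mode the detector
    consumes) the per-leaflet reference is averaged over frames.
    """
    if series.lipid_ref_z is None:
        raise GeometryError("series carries no lipid_ref_z; cannot place membrane")
    if mode != "static":
        raise ValueError(f"unknown geometry mode: {mode!r}")
    lower = float(series.lipid_ref_z[:, 0].mean())
    upper = float(series.lipid_ref_z[:, 1].mean())
    if upper - lower < _MIN_LEAFLET_SEPARATION:
        raise DegenerateMembraneError(
            f"leaflet means separated by {upper - lower:.3f} nm "
            f"(< {_MIN_LEAFLET_SEPARATION} nm); not a bilayer"
        )
    return MembraneGeometry(lower, upper, crossing_offset)


def _regions(z: np.ndarray, geom: MembraneGeometry) -> np.ndarray:
    """-1 below the lower plane, +1 at/above the upper plane, else 0.

    Both far-side boundaries are closed: landing exactly on a crossing
    plane counts as having arrived in that bulk.
    """
    out = np.zeros(z.shape, dtype=np.int8)
    out[z <= geom.lower_plane] = -1
    out[z >= geom.upper_plane] = 1
    return out


def detect_crossings(series: ZSeries, geom: MembraneGeometry) -> list[CrossingEvent]:
    """Detect complete translocations in a recentred series.

    Requires the geometry midplane to sit near z = 0 (the series must have
    been through :func:`tbcperm.trajio.recentre_and_wrap`) and both
    crossing planes to lie inside the box.  Events are returned sorted by
    ``end_time``.
    """
    if abs(geom.midplane) > 0.25 * geom.thickness:
        raise GeometryError(
            f"membrane midplane at {geom.midplane:.2f} nm; series does not "
            "look recentred (run recentre_and_wrap first)"
        )
    half_box = float(series.box_z.min()) / 2.0
    if geom.lower_plane <= -half_box or geom.upper_plane >= half_box:
        raise GeometryError(
            "crossing planes fall outside the box; no bulk region exists"
        )

    regions = _regions(series.z, geom)
    if series.jumps is not None:
        jump_any = series.jumps
    else:
        box = series.box_z[1:, None]
        jump_any = np.abs(np.diff(series.z, axis=0)) > box / 2.0
    # prefix count of jumps: jumps[p] flags the (p, p+1) frame pair
    jump_prefix = np.zeros((series.n_frames, series.n_solutes), dtype=np.int64)
    if series.n_frames > 1:
        np.cumsum(jump_any, axis=0, out=jump_prefix[1:])

    events: list[CrossingEvent] = []
    times = series.times
    for s in range(series.n_solutes):
        r = regions[:, s]
        bulk_idx = np.nonzero(r)[0]
        if bulk_idx.size == 0:
            continue
        vals = r[bulk_idx]
        flips = np.nonzero(np.diff(vals))[0]
        jp = jump_prefix[:, s]
        for f in flips:
            i_src = int(bulk_idx[f])      # last frame in source bulk
            i_dst = int(bulk_idx[f + 1])  # first frame in opposite bulk
            if jp[i_dst] - jp[i_src] > 0:
                # path wrapped through the periodic boundary: assignment
                # transfers, but no membrane passage occurred
                continue
            events.append(
                CrossingEvent(
                    solute_index=s,
                    start_time=float(times[i_src]),
                    end_time=float(times[i_dst]),
                    direction="up" if vals[f + 1] > 0 else "down",
                )
            )
    events.sort(key=lambda e: (e.end_time, e.solute_index))
    return events


def rate_series(
    events: list[CrossingEvent],
    total_time: float,
    checkpoint_interval: float = 10.0,
) -> RateSeries:
    """Running rate k(t) = events so far / t at regular checkpoints.

    Events are counted at their completion time regardless of direction
    (the flux through the bilayer is bidirectional at equilibrium).
    """
    if not total_time > 0:
        raise ValueError("total_time must be positive")
    if not checkpoint_interval > 0:
        raise ValueError("checkpoint_interval must be positive")
    end_times = np.sort(np.asarray([e.end_time for e in events], dtype=float))
    if end_times.size and end_times[-1] > total_time:
        raise ValueError(
            f"event at t = {end_times[-1]} ns lies beyond total_time = {total_time} ns"
        )
    n_cp = int(np.floor(total_time / checkpoint_interval + 1e-9))
    if n_cp < 1:
        raise ValueError("horizon shorter than one checkpoint interval")
    checkpoints = checkpoint_interval * np.arange(1, n_cp + 1)
    cumulative = np.searchsorted(end_times, checkpoints, side="right")
    k = cumulative / checkpoints
    dk_dt = np.diff(k) / np.diff(checkpoints) if n_cp > 1 else np.empty(0)
    return RateSeries(
        checkpoint_times=checkpoints,
        cumulative_events=cumulative.astype(np.int64),
        k=k,
        dk_dt=dk_dt,
    )


def events_table(events: list[CrossingEvent]) -> pd.DataFrame:
    """Events as a tidy table (exportable to TSV)."""
    return pd.DataFrame(
        {
            "solute_index": [e.solute_index for e in events],
            "start_ns": [e.start_time for e in events],
            "end_ns": [e.end_time for e in events],
            "direction": [e.direction for e in events],
        }
    )
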