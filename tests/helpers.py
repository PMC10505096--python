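"""Independent oracles shared by the test modules.

These deliberately re-derive results by the most transparent route
available (frame-by-frame scanning, literal formulas) and never call the
code paths they are used to check.
"""

from __future__ import annotations

import numpy as np

from tbcperm.tbc import MembraneGeometry
from tbcperm.trajio import ZSeries


def brute_force_crossings(
    series: ZSeries, geom: MembraneGeometry
) -> list[tuple[int, float, float, str]]:
    """Frame-by-frame region-sequence scanner (reference implementation).

    Walks every frame of every solute with explicit state, recording a
    translocation whenever a solute last assigned to one bulk region is
    seen in the opposite one without a periodic jump in between.
    Returns (solute, start_ns, end_ns, direction) tuples.
    """
    events = []
    lower, upper = geom.lower_plane, geom.upper_plane
    for s in range(series.n_solutes):
        state = 0
        last_src_time = None
        jump_pending = False
        for i in range(series.n_frames):
            z = series.z[i, s]
            if i > 0:
                if abs(z - series.z[i - 1, s]) > series.box_z[i] / 2.0:
                    jump_pending = True
            region = -1 if z <= lower else (1 if z >= upper else 0)
            if region == 0:
                continue
            if state != 0 and region != state and not jump_pending:
                events.append(
                    (
                        s,
                        float(last_src_time),
                        float(series.times[i]),
                        "up" if region > 0 else "down",
                    )
                )
            state = region
            last_src_time = series.times[i]
            jump_pending = False
    events.sort(key=lambda e: (e[2], e[0]))
    return events


def random_walk_series(
    rng: np.random.Generator,
    n_frames: int = 300,
    n_solutes: int = 2,
    box_z: float = 12.0,
    step_sigma: float = 1.2,
    jump_prob: float = 0.02,
) -> ZSeries:
    """Random walk with occasional teleports across the periodic box.

    The teleports produce frame pairs that the detector must classify as
    periodic jumps, which makes these series an aggressive stress test
    for the jump-transfer rule.
    """
    half = box_z / 2.0
    z = np.empty((n_frames, n_solutes))
    z[0] = rng.uniform(-half, half, size=n_solutes)
    for i in range(1, n_frames):
        step = rng.normal(0.0, step_sigma, size=n_solutes)
        teleport = rng.uniform(size=n_solutes) < jump_prob
        nxt = np.where(teleport, -z[i - 1], z[i - 1] + step)
        z[i] = (nxt + half) % box_z - half
    return ZSeries(
        times=np.arange(n_frames, dtype=float) * 0.1,
        z=z,
        box_z=box_z,
        temperature=300.0,
        lipid_ref_z=np.array([-2.0, 2.0]),
        label="random-walk",
    )


def sig_figs(x: float, n: int = 3) -> float:
    """Round to n significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (n - 1))
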