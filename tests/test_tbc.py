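"""Crossing detection: geometry, the counting state machine, rate series."""

import numpy as np
import pytest
from helpers import brute_force_crossings, random_walk_series

from tbcperm import synth, tbc, trajio
from tbcperm.errors import DegenerateMembraneError, GeometryError
from tbcperm.tbc import (
    CrossingEvent,
    MembraneGeometry,
    detect_crossings,
    estimate_membrane_geometry,
    events_table,
    rate_series,
)
from tbcperm.trajio import ZSeries


def series_from_z(z, times=None, box=12.0, ref=(-2.0, 2.0)):
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[0] == 1:
        z = z.T
    if times is None:
        times = np.arange(z.shape[0], dtype=float)
    return ZSeries(
        times=times,
        z=z,
        box_z=box,
        temperature=300.0,
        lipid_ref_z=np.asarray(ref),
    )


GEOM = MembraneGeometry(-2.0, 2.0, 1.0)


class TestMembraneGeometry:
    def test_constant_reference(self):
        geom = estimate_membrane_geometry(series_from_z([0.0, 0.0]))
        assert geom.lower_boundary == -2.0
        assert geom.upper_boundary == 2.0
        assert geom.midplane == 0.0
        assert geom.lower_plane == -3.0 and geom.upper_plane == 3.0

    def test_noisy_reference_within_sigma(self, rng):
        n = 4000
        ref = np.column_stack(
            [rng.normal(-2.0, 0.1, n), rng.normal(2.0, 0.1, n)]
        )
        series = ZSeries(
            times=np.arange(n, dtype=float),
            z=np.zeros((n, 1)),
            box_z=12.0,
            temperature=300.0,
            lipid_ref_z=ref,
        )
        geom = estimate_membrane_geometry(series)
        # sample mean of 4000 draws at sigma 0.1: SE ~ 0.0016
        assert geom.lower_boundary == pytest.approx(-2.0, abs=0.01)
        assert geom.upper_boundary == pytest.approx(2.0, abs=0.01)

    def test_degenerate_membrane(self):
        with pytest.raises(DegenerateMembraneError):
            estimate_membrane_geometry(series_from_z([0.0, 0.0], ref=(-0.2, 0.2)))

    def test_missing_reference(self):
        series = ZSeries(
            times=[0.0], z=[[0.0]], box_z=12.0, temperature=300.0
        )
        with pytest.raises(GeometryError):
            estimate_membrane_geometry(series)


class TestDetector:
    def test_oscillation_in_one_bulk_no_events(self):
        z = [-5.0, -4.0, -5.5, -3.5, -5.0, -4.2]
        assert detect_crossings(series_from_z(z), GEOM) == []

    def test_grazing_membrane_no_events(self):
        # enters the membrane-adjacent region repeatedly, never commits
        z = [-5.0, -1.0, -5.0, 2.5, -5.0, 0.0, -5.0]
        assert detect_crossings(series_from_z(z), GEOM) == []

    def test_single_transit(self):
        z = [-5.0, -1.0, 1.0, 5.0]
        events = detect_crossings(series_from_z(z), GEOM)
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "up"
        assert ev.start_time == 0.0  # last frame in the source bulk
        assert ev.end_time == 3.0    # first frame beyond the far plane

    def test_exact_plane_touch_counts(self):
        # far boundary is closed: landing exactly on the plane is arrival
        z = [-5.0, 0.0, 3.0]
        assert len(detect_crossings(series_from_z(z), GEOM)) == 1

    def test_five_transits_three_aborts(self):
        legs = [-5.0, -1.5] * 3          # three aborted half-entries
        legs += [-5.0, 0.0, 5.0]         # transit 1 (up)
        legs += [0.0, -5.0]              # transit 2 (down)
        legs += [0.0, 5.0]               # transit 3 (up)
        legs += [0.0, -5.0]              # transit 4 (down)
        legs += [0.0, 5.0]               # transit 5 (up)
        events = detect_crossings(series_from_z(legs), GEOM)
        assert len(events) == 5
        assert [e.direction for e in events] == ["up", "down", "up", "down", "up"]

    def test_periodic_jump_transfers_without_event(self):
        z = [-5.0, -5.8, 5.8, 5.0, 0.0, -5.0]
        series = trajio.recentre_and_wrap(series_from_z(z))
        events = detect_crossings(series, GEOM)
        # the wrap move -5.8 -> 5.8 is not a crossing, but it hands the
        # solute to the upper bulk, so the later downward transit counts
        assert len(events) == 1
        assert events[0].direction == "down"

    def test_starts_inside_membrane_unassigned(self):
        z = [0.0, 1.0, 5.0, 0.0, -5.0]
        events = detect_crossings(series_from_z(z), GEOM)
        assert len(events) == 1  # only the later up->down transit counts
        assert events[0].direction == "down"

    def test_unrecentred_series_rejected(self):
        geom = MembraneGeometry(1.0, 5.0, 0.5)
        with pytest.raises(GeometryError, match="recentred"):
            detect_crossings(series_from_z([0.0, 0.0]), geom)

    def test_planes_outside_box_rejected(self):
        geom = MembraneGeometry(-5.5, 5.5, 1.0)
        with pytest.raises(GeometryError, match="box"):
            detect_crossings(series_from_z([0.0, 0.0]), geom)


class TestDetectorProperties:
    def test_oracle_equivalence_on_random_walks(self, rng):
        for _ in range(200):
            series = trajio.recentre_and_wrap(random_walk_series(rng))
            got = [
                (e.solute_index, e.start_time, e.end_time, e.direction)
                for e in detect_crossings(series, GEOM)
            ]
            assert got == brute_force_crossings(series, GEOM)

    def test_time_reversal_symmetry(self, rng):
        for _ in range(50):
            series = trajio.recentre_and_wrap(random_walk_series(rng, n_frames=200))
            fwd = detect_crossings(series, GEOM)
            rev = trajio.recentre_and_wrap(
                ZSeries(
                    times=series.times[-1] - series.times[::-1],
                    z=series.z[::-1],
                    box_z=series.box_z[::-1],
                    temperature=series.temperature,
                    lipid_ref_z=series.lipid_ref_z,
                )
            )
            bwd = detect_crossings(rev, GEOM)
            assert len(fwd) == len(bwd)
            assert sum(e.direction == "up" for e in fwd) == sum(
                e.direction == "down" for e in bwd
            )

    def test_stride_refinement_never_loses_events(self):
        # oscillating continuous path; coarser output frames may miss
        # plane touches but refinement must never lose a transit
        t = np.arange(0.0, 200.0, 0.05)
        z = 5.2 * np.sin(0.25 * t)
        dense = series_from_z(z, times=t)
        counts = []
        for stride in (64, 16, 4, 1):
            sub = series_from_z(z[::stride], times=t[::stride])
            counts.append(len(detect_crossings(sub, GEOM)))
        assert counts == sorted(counts)
        assert counts[-1] == len(detect_crossings(dense, GEOM)) > 0


class TestRateSeries:
    def test_no_events_zero_rate(self):
        rates = rate_series([], total_time=100.0, checkpoint_interval=10.0)
        assert np.all(rates.k == 0)
        assert np.all(rates.cumulative_events == 0)

    def test_uniform_events_rate_one(self):
        events = [
            CrossingEvent(0, start_time=t - 0.5, end_time=t, direction="up")
            for t in np.arange(1.0, 101.0)
        ]
        rates = rate_series(events, total_time=100.0, checkpoint_interval=10.0)
        assert rates.k[-1] == pytest.approx(1.0)
        assert rates.cumulative_events[-1] == 100
        # invariant: k is exactly cumulative / time at every checkpoint
        np.testing.assert_array_equal(
            rates.k, rates.cumulative_events / rates.checkpoint_times
        )

    def test_poisson_stream_recovers_rate(self, rng):
        true_rate, horizon = 0.5, 2000.0
        n = rng.poisson(true_rate * horizon)
        ends = np.sort(rng.uniform(0.0, horizon, size=n))
        events = [
            CrossingEvent(0, start_time=t - 1e-3, end_time=t, direction="up")
            for t in ends
        ]
        rates = rate_series(events, total_time=horizon, checkpoint_interval=10.0)
        sigma = np.sqrt(n) / horizon
        assert abs(rates.k[-1] - true_rate) < 3 * sigma

    def test_event_beyond_horizon_rejected(self):
        events = [CrossingEvent(0, 0.0, 150.0, "up")]
        with pytest.raises(ValueError, match="beyond"):
            rate_series(events, total_time=100.0)

    def test_events_table_columns(self):
        events = [CrossingEvent(1, 0.0, 5.0, "up")]
        table = events_table(events)
        assert list(table.columns) == ["solute_index", "start_ns", "end_ns", "direction"]
        assert table.iloc[0]["direction"] == "up"
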