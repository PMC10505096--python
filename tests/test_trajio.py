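"""Text-dialect round trips, recentring/wrapping, and container loading."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tbcperm import trajio
from tbcperm.errors import (
    CorruptInputError,
    DialectError,
    EmptyDataError,
    GeometryError,
    SelectionError,
)
from tbcperm.trajio import ZSeries, read_zseries_text, recentre_and_wrap, write_zseries_text


def make_series(z, box=12.0, times=None, **kw):
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[0] == 1:
        z = z.T
    if times is None:
        times = np.arange(z.shape[0], dtype=float)
    return ZSeries(times=times, z=z, box_z=box, temperature=300.0, **kw)


class TestZSeriesValidation:
    def test_rejects_nonmonotonic_times(self):
        with pytest.raises(CorruptInputError):
            make_series([0.0, 1.0, 2.0], times=np.array([0.0, 2.0, 1.0]))

    def test_rejects_negative_box(self):
        with pytest.raises(CorruptInputError):
            make_series([0.0, 1.0], box=-1.0)

    def test_rejects_zero_temperature(self):
        with pytest.raises(CorruptInputError):
            ZSeries(times=[0.0], z=[[0.0]], box_z=12.0, temperature=0.0)

    def test_rejects_length_mismatch(self):
        with pytest.raises(CorruptInputError):
            ZSeries(times=[0.0, 1.0], z=np.zeros((3, 2)), box_z=12.0, temperature=300.0)


@st.composite
def zseries_strategy(draw):
    n_frames = draw(st.integers(min_value=1, max_value=12))
    n_solutes = draw(st.integers(min_value=1, max_value=3))
    dt = draw(st.floats(min_value=1e-3, max_value=10.0, allow_nan=False))
    t0 = draw(st.floats(min_value=0.0, max_value=5.0, allow_nan=False))
    z = draw(
        st.lists(
            st.lists(
                st.floats(min_value=-6.0, max_value=6.0, allow_nan=False, width=64),
                min_size=n_solutes,
                max_size=n_solutes,
            ),
            min_size=n_frames,
            max_size=n_frames,
        )
    )
    temp = draw(st.floats(min_value=50.0, max_value=700.0, allow_nan=False))
    label = draw(st.text(alphabet="abcdefghij-_0123456789", max_size=12))
    with_ref = draw(st.booleans())
    ref = np.array([-2.0, 2.0]) if with_ref else None
    return ZSeries(
        times=t0 + dt * np.arange(n_frames),
        z=np.asarray(z),
        box_z=12.0,
        temperature=temp,
        lipid_ref_z=ref,
        label=label,
    )


class TestTextDialect:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(zseries_strategy())
    def test_write_read_identity(self, tmp_path_factory, series):
        path = tmp_path_factory.mktemp("dialect") / "series.dat"
        write_zseries_text(series, path)
        back = read_zseries_text(path)
        np.testing.assert_array_equal(back.times, series.times)
        np.testing.assert_array_equal(back.z, series.z)
        np.testing.assert_array_equal(back.box_z, series.box_z)
        assert back.temperature == series.temperature
        assert back.label == series.label
        if series.lipid_ref_z is None:
            assert back.lipid_ref_z is None
        else:
            np.testing.assert_array_equal(back.lipid_ref_z, series.lipid_ref_z)

    def test_large_roundtrip_is_bit_identical(self, tmp_path):
        rng = np.random.default_rng(3)
        series = make_series(rng.uniform(-6, 6, size=(10_000, 2)))
        path = tmp_path / "big.dat"
        write_zseries_text(series, path)
        back = read_zseries_text(path)
        np.testing.assert_array_equal(back.z, series.z)
        np.testing.assert_array_equal(back.times, series.times)

    def test_missing_header_key_raises(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("# label: x\n# box_z_nm: 12.0\n0.0 1.0\n")
        with pytest.raises(DialectError, match="temperature_K"):
            read_zseries_text(path)

    def test_ragged_rows_raise(self, tmp_path):
        path = tmp_path / "ragged.dat"
        path.write_text(
            "# label: x\n# temperature_K: 300\n# box_z_nm: 12.0\n"
            "0.0 1.0\n1.0 1.0 2.0\n"
        )
        with pytest.raises(DialectError, match="ragged"):
            read_zseries_text(path)

    def test_headers_only_raises_empty(self, tmp_path):
        path = tmp_path / "empty.dat"
        path.write_text("# label: x\n# temperature_K: 300\n# box_z_nm: 12.0\n")
        with pytest.raises(EmptyDataError):
            read_zseries_text(path)

    def test_meta_survives_roundtrip(self, tmp_path):
        series = make_series([0.0, 1.0], meta={"true_events": "5"})
        path = tmp_path / "meta.dat"
        write_zseries_text(series, path)
        assert read_zseries_text(path).meta["true_events"] == "5"


class TestRecentreAndWrap:
    def test_identity_when_centred(self):
        series = make_series([[0.0, 1.0], [2.0, -3.0]])
        out = recentre_and_wrap(series, 0.0)
        np.testing.assert_array_equal(out.z, series.z)

    def test_wrap_arithmetic(self):
        series = make_series([6.1, 0.0])
        out = recentre_and_wrap(series, 0.0)
        assert out.z[0, 0] == pytest.approx(-6.0 + 0.1)

    def test_midplane_shift(self):
        series = make_series([1.5, 2.5])
        out = recentre_and_wrap(series, 1.0)
        np.testing.assert_allclose(out.z[:, 0], [0.5, 1.5])

    def test_idempotent(self, rng):
        series = make_series(rng.uniform(-8, 8, size=(50, 3)))
        once = recentre_and_wrap(series, 0.4)
        twice = recentre_and_wrap(once, 0.0)
        np.testing.assert_array_equal(once.z, twice.z)
        np.testing.assert_array_equal(once.jumps, twice.jumps)

    def test_boundary_crossing_flagged_once(self):
        # path drifts across the +box/2 boundary exactly once
        series = make_series([5.0, 5.9, -5.9, -5.0])
        out = recentre_and_wrap(series, 0.0)
        assert out.jumps.sum() == 1
        assert bool(out.jumps[1, 0])

    def test_midplane_length_mismatch(self):
        series = make_series([0.0, 1.0])
        with pytest.raises(GeometryError):
            recentre_and_wrap(series, np.array([0.0, 0.0, 0.0]))

    def test_result_lies_in_box(self, rng):
        series = make_series(rng.uniform(-30, 30, size=(40, 2)))
        out = recentre_and_wrap(series, 2.5)
        assert np.all(out.z >= -6.0) and np.all(out.z < 6.0)


class TestUnwrap:
    def test_unwrap_restores_continuity(self):
        # drifting path that wraps twice
        t = np.arange(100, dtype=float)
        true = 0.25 * t  # reaches 24.75 nm
        series = make_series((true + 6.0) % 12.0 - 6.0, times=t)
        un = trajio.unwrap(series)
        np.testing.assert_allclose(un[:, 0], true, atol=1e-10)


@pytest.fixture()
def pdb_trajectory(tmp_path):
    """Three-model PDB: one 'solute' atom at z = 0, 10, 20 A (0/1/2 nm)."""
    models = []
    for i, zval in enumerate((0.0, 10.0, 20.0), start=1):
        models.append(
            f"MODEL     {i:>4}\n"
            f"CRYST1   50.000   50.000  120.000  90.00  90.00  90.00 P 1           1\n"
            f"ATOM      1  C   SOL A   1      10.000  10.000{zval:8.3f}  1.00  0.00           C\n"
            f"ATOM      2  P   DPP B   2      10.000  20.000 -20.000  1.00  0.00           P\n"
            f"ATOM      3  P   DPP B   3      20.000  10.000  20.000  1.00  0.00           P\n"
            "ENDMDL\n"
        )
    path = tmp_path / "traj.pdb"
    path.write_text("".join(models) + "END\n")
    return path


class TestContainerAdapter:
    def test_identity_extraction(self, pdb_trajectory):
        mda = pytest.importorskip("MDAnalysis")  # noqa: F841
        series = trajio.load_zseries(
            pdb_trajectory, pdb_trajectory, "resname SOL", "name P"
        )
        np.testing.assert_allclose(series.z[:, 0], [0.0, 1.0, 2.0], atol=1e-6)
        assert series.n_frames == 3
        np.testing.assert_allclose(series.box_z, 12.0)
        np.testing.assert_allclose(series.lipid_ref_z[0], [-2.0, 2.0], atol=1e-6)

    def test_stride_decimation(self, pdb_trajectory):
        pytest.importorskip("MDAnalysis")
        series = trajio.load_zseries(
            pdb_trajectory, pdb_trajectory, "resname SOL", "name P", stride=2
        )
        assert series.n_frames == 2  # ceil(3 / 2)

    def test_empty_selection_raises(self, pdb_trajectory):
        pytest.importorskip("MDAnalysis")
        with pytest.raises(SelectionError):
            trajio.load_zseries(
                pdb_trajectory, pdb_trajectory, "resname NOPE", "name P"
            )
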