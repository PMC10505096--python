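"""Read, write and recentre solute z-coordinate time series.

The pipeline only ever needs the z-coordinate of each solute copy, the box
length along z, and (optionally) a per-leaflet lipid headgroup reference.
Everything is carried in a :class:`ZSeries` with fixed internal units:
nanometres for lengths, nanoseconds for times, kelvin for temperature.
Unit conversions happen only at the I/O boundary.

Two input routes exist:

* a plain whitespace-separated text dialect (the interchange format, also
  emitted by :mod:`tbcperm.synth`), handled by :func:`read_zseries_text`
  and :func:`write_zseries_text`;
* standard MD trajectory containers (XTC/TRR/DCD + PDB/GRO topology) via
  an optional MDAnalysis adapter, :func:`load_zseries`.  The core package
  never requires the binary-format libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    CorruptInputError,
    DialectError,
    EmptyDataError,
    FormatError,
    GeometryError,
    SelectionError,
)

__all__ = [
    "ZSeries",
    "read_zseries_text",
    "write_zseries_text",
    "recentre_and_wrap",
    "unwrap",
    "load_zseries",
]

_DIALECT_TAG = "tbcperm-zseries v1"


@dataclass
class ZSeries:
    """Per-solute z-position time series with box geometry and temperature.

    Parameters
    ----------
    times : (n_frames,) array, ns, strictly increasing.
    z : (n_frames, n_solutes) array, nm.  One column per solute copy.
    box_z : scalar or (n_frames,) array, nm.  Box length along z.
    temperature : float, K.
    lipid_ref_z : optional (2,) or (n_frames, 2) array, nm.  Mean headgroup
        z of the (lower, upper) leaflet.
    label : compound name.
    jumps : optional (n_frames-1, n_solutes) bool array marking frame pairs
        whose displacement exceeds half the box (periodic image jump).
        Filled in by :func:`recentre_and_wrap`.
    meta : free-form provenance / ground-truth dictionary.
    """

    times: np.ndarray
    z: np.ndarray
    box_z: np.ndarray
    temperature: float
    lipid_ref_z: np.ndarray | None = None
    label: str = ""
    jumps: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim == 1:  # single solute passed as a flat vector
            self.z = self.z[:, None]
        n = self.times.shape[0]
        if n == 0:
            raise EmptyDataError("ZSeries must contain at least one frame")
        if self.z.shape[0] != n:
            raise CorruptInputError(
                f"z has {self.z.shape[0]} frames but times has {n}"
            )
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise CorruptInputError("timestamps must be strictly increasing")
        self.box_z = np.broadcast_to(
            np.asarray(self.box_z, dtype=float), (n,)
        ).copy()
        if np.any(self.box_z <= 0):
            raise CorruptInputError("box_z must be positive for all frames")
        self.temperature = float(self.temperature)
        if not self.temperature > 0:
            raise CorruptInputError("temperature must be positive (kelvin)")
        if self.lipid_ref_z is not None:
            ref = np.asarray(self.lipid_ref_z, dtype=float)
            if ref.ndim == 1:
                ref = np.broadcast_to(ref, (n, 2)).copy()
            if ref.shape != (n, 2):
                raise GeometryError(
                    f"lipid_ref_z must have shape (2,) or ({n}, 2), got {ref.shape}"
                )
            self.lipid_ref_z = ref

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_solutes(self) -> int:
        return self.z.shape[1]

    @property
    def total_time(self) -> float:
        """Trajectory span in ns (first frame taken as the origin)."""
        return float(self.times[-1] - self.times[0])

    def constant_box_z(self) -> float:
        if not np.all(self.box_z == self.box_z[0]):
            raise GeometryError("series has a per-frame box; no single box_z")
        return float(self.box_z[0])


def write_zseries_text(series: ZSeries, path: str | Path) -> None:
    """Write *series* in the text dialect (full float precision).

    The dialect stores a constant box (and, if present, a constant leaflet
    reference); series with per-frame geometry must be exported another
    way.
    """
    path = Path(path)
    box = series.constant_box_z()
    lines = [
        f"# {_DIALECT_TAG}",
        f"# label: {series.label}",
        f"# temperature_K: {series.temperature!r}",
        f"# box_z_nm: {box!r}",
    ]
    if series.lipid_ref_z is not None:
        ref = series.lipid_ref_z
        if not np.all(ref == ref[0]):
            raise GeometryError("dialect only stores a constant lipid_ref_z")
        lines.append(
            f"# lipid_ref_z_nm: {float(ref[0, 0])!r} {float(ref[0, 1])!r}"
        )
    for key, val in series.meta.items():
        lines.append(f"# meta {key}: {val}")
    lines.append(
        "# columns: time_ns " + " ".join(f"z_{i + 1}" for i in range(series.n_solutes))
    )
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        for t, row in zip(series.times, series.z):
            fh.write(
                "%.17g %s\n" % (t, " ".join("%.17g" % v for v in row))
            )


def read_zseries_text(path: str | Path) -> ZSeries:
    """Parse the text dialect written by :func:`write_zseries_text`."""
    path = Path(path)
    header: dict[str, str] = {}
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    width: int | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip()
                    if key.startswith("meta "):
                        meta[key[5:].strip()] = val.strip()
                    else:
                        header[key] = val.strip()
                continue
            parts = line.split()
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise DialectError(f"{path}:{lineno}: non-numeric field") from exc
            if width is None:
                width = len(values)
                if width < 2:
                    raise DialectError(
                        f"{path}:{lineno}: need at least time and one z column"
                    )
            elif len(values) != width:
                raise DialectError(
                    f"{path}:{lineno}: ragged row ({len(values)} fields, expected {width})"
                )
            rows.append(values)
    for key in ("temperature_K", "box_z_nm", "label"):
        if key not in header:
            raise DialectError(f"{path}: missing required header key '{key}'")
    if not rows:
        raise EmptyDataError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    lipid_ref = None
    if "lipid_ref_z_nm" in header:
        lo, hi = (float(v) for v in header["lipid_ref_z_nm"].split())
        lipid_ref = np.array([lo, hi])
    return ZSeries(
        times=data[:, 0],
        z=data[:, 1:],
        box_z=float(header["box_z_nm"]),
        temperature=float(header["temperature_K"]),
        lipid_ref_z=lipid_ref,
        label=header["label"],
        meta=meta,
    )


def _wrap(z: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap into [-box/2, +box/2) per frame."""
    return (z + box / 2.0) % box - box / 2.0


def recentre_and_wrap(series: ZSeries, midplane: float | np.ndarray = 0.0) -> ZSeries:
    """Shift so the membrane midplane sits at z = 0, wrap into the box.

    Every solute z is shifted by the (scalar or per-frame) *midplane* and
    wrapped into ``[-box_z/2, +box_z/2)``.  Frame pairs whose wrapped
    displacement exceeds half the box are flagged in ``jumps``: these are
    periodic-image moves, and the crossing detector must not read them as
    physical passage through the membrane.

    Idempotent: recentring an already-centred series (midplane 0) returns
    an equal series.
    """
    mid = np.asarray(midplane, dtype=float)
    if mid.ndim == 0:
        mid = np.broadcast_to(mid, (series.n_frames,))
    if mid.shape != (series.n_frames,):
        raise GeometryError(
            f"midplane length {mid.shape} does not match {series.n_frames} frames"
        )
    box = series.box_z[:, None]
    z = _wrap(series.z - mid[:, None], box)
    jumps = None
    if series.n_frames > 1:
        jumps = np.abs(np.diff(z, axis=0)) > (box[1:] / 2.0)
    lipid_ref = None
    if series.lipid_ref_z is not None:
        # leaflet planes sit well inside the box: shift without wrapping so
        # the (lower, upper) identity survives
        lipid_ref = series.lipid_ref_z - mid[:, None]
    return replace(series, z=z, lipid_ref_z=lipid_ref, jumps=jumps)


def unwrap(series: ZSeries) -> np.ndarray:
    """Return continuous (unwrapped) z, removing periodic jumps.

    Used for diffusion (MSD) analysis; the crossing detector works on the
    wrapped coordinates instead.
    """
    z = series.z
    box = series.box_z[1:, None]
    dz = np.diff(z, axis=0)
    dz -= box * np.round(dz / box)
    out = np.empty_like(z)
    out[0] = z[0]
    out[1:] = z[0] + np.cumsum(dz, axis=0)
    return out


def load_zseries(
    path: str | Path,
    topology: str | Path,
    solute_selector: str,
    lipid_selector: str,
    stride: int = 1,
) -> ZSeries:
    """Extract a :class:`ZSeries` from a standard MD trajectory container.

    Requires the optional MDAnalysis dependency (``pip install
    tbcperm[traj]``).  Solute position is the centre of mass of the
    selected atoms, one column per solute residue; the leaflet reference is
    the mean z of selected headgroup atoms on each side of the lipids'
    overall mean z.  Lengths are converted Å → nm and times ps → ns.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise FormatError(
            "reading trajectory containers requires MDAnalysis "
            "(install the 'traj' extra)"
        ) from exc

    path, topology = Path(path), Path(topology)
    if not path.exists():
        raise FormatError(f"trajectory file not found: {path}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    try:
        universe = mda.Universe(str(topology), str(path))
    except Exception as exc:
        raise FormatError(f"cannot read trajectory {path}: {exc}") from exc

    solute = universe.select_atoms(solute_selector)
    if len(solute) == 0:
        raise SelectionError(f"solute selector matched no atoms: {solute_selector!r}")
    lipid = universe.select_atoms(lipid_selector)
    if len(lipid) == 0:
        raise SelectionError(f"lipid selector matched no atoms: {lipid_selector!r}")
    copies = [res.atoms.intersection(solute) for res in solute.residues]

    times, z_rows, box_rows, ref_rows = [], [], [], []
    for ts in universe.trajectory[::stride]:
        times.append(ts.time / 1000.0)  # ps -> ns
        z_rows.append([ag.center_of_mass()[2] / 10.0 for ag in copies])
        box_rows.append(ts.dimensions[2] / 10.0)
        lz = lipid.positions[:, 2] / 10.0
        mu = lz.mean()
        lower = lz[lz < mu]
        upper = lz[lz >= mu]
        if len(lower) == 0 or len(upper) == 0:
            raise GeometryError("cannot split lipid reference atoms into leaflets")
        ref_rows.append([lower.mean(), upper.mean()])

    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        raise CorruptInputError(f"{path}: non-monotonic trajectory timestamps")
    return ZSeries(
        times=times_arr,
        z=np.asarray(z_rows),
        box_z=np.asarray(box_rows),
        temperature=_guess_temperature(universe),
        lipid_ref_z=np.asarray(ref_rows),
        label=path.stem,
    )


def _guess_temperature(universe) -> float:
    """Trajectory containers rarely store T; fall back to 300 K."""
    data = getattr(universe.trajectory.ts, "data", {})
    temp = data.get("temperature", None)
    if temp is None or not math.isfinite(temp) or temp <= 0:
        return 300.0
    return float(temp)
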