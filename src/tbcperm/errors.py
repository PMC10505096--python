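"""Exception hierarchy for the tbcperm pipeline.

Domain errors on scalar arguments (negative permeabilities, non-positive
areas, ...) raise plain :class:`ValueError`; the classes below mark failure
modes a caller may reasonably want to catch individually, e.g. to map them
to exit codes in the command-line driver.
"""


class TbcpermError(Exception):
    """Base class for all tbcperm-specific errors."""


class DialectError(TbcpermError):
    """Malformed z-series text file (missing header keys, ragged rows, ...)."""


class FormatError(TbcpermError):
    """Unsupported or unreadable trajectory container."""


class SelectionError(TbcpermError):
    """An atom-selection expression matched no atoms."""


class CorruptInputError(TbcpermError):
    """Input violates a structural invariant (non-monotonic timestamps, ...)."""


class GeometryError(TbcpermError):
    """Membrane geometry is missing, inconsistent, or incompatible."""


class DegenerateMembraneError(GeometryError):
    """Leaflet reference planes are too close to define a bilayer."""


class NonConvergenceError(TbcpermError):
    """The running rate never satisfies the steady-state criterion.

    Usually means the trajectory is too short for the solute's crossing
    rate; carries the last observed |dk/dt| when available.
    """

    def __init__(self, message: str, last_dk_dt: float | None = None):
        super().__init__(message)
        self.last_dk_dt = last_dk_dt


class InsufficientDataError(TbcpermError):
    """Too few points for the requested fit or statistic."""


class EmptyDataError(TbcpermError):
    """An operation was left with no data (all frames skipped, all rows trimmed)."""


class IntegrityError(TbcpermError):
    """Packaged fixture data failed its checksum."""


class StabilityError(TbcpermError):
    """Langevin time step too large for the requested barrier."""


class StageError(TbcpermError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
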