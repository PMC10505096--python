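"""Log-log calibration of high-temperature permeability to 37 degC.

Crossing statistics converge in reachable simulation time only at
elevated temperature (here 127 degC and 167 degC).  Across a training
library of CNS compounds, the simulated single-bilayer permeability at
high temperature and the experimental transwell apparent permeability at
25-37 degC are related, to good approximation, by a straight line in
log10-log10 space:

    log10 P_app,37C = m * log10 P_sim,highT + c

Fitting (m, c) by ordinary least squares turns a single high-temperature
simulation of a new compound into a ranked prediction of its apparent
permeability.  This module fits, predicts, scores predictions by their
order-of-magnitude error |log10 P_exp - log10 P_pred|, ranks compounds,
and probes how stable the fitted slope is against training-set size by
exhaustive (or seeded random) regression over all n-compound subsets.

Two frozen calibration lines for the 167 degC library are shipped in two
precisions, because downstream uses rounded them differently:
``CAL_167C_FULL`` (1.124, -4.819) and ``CAL_167C_ROUNDED`` (1.12, -4.82);
``CAL_127C`` is (1.17, -3.73).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyDataError, InsufficientDataError

__all__ = [
    "CompoundRecord",
    "CalibrationModel",
    "SubsetStabilityResult",
    "ErrorReport",
    "RankedCompound",
    "CAL_167C_FULL",
    "CAL_167C_ROUNDED",
    "CAL_127C",
    "fit_loglog",
    "predict_papp",
    "oom_error",
    "evaluate_errors",
    "subset_stability",
    "rank_compounds",
]


@dataclass
class CompoundRecord:
    """One compound: simulated permeabilities per temperature plus the
    experimental apparent permeability and its literature source.

    ``p_sim`` maps a temperature label ("127C", "167C") to P_sim in cm/s;
    entries may be absent when the rate never converged at that
    temperature.  All stored permeabilities must be positive (their
    logarithms must exist).
    """

    name: str
    index: int | None = None
    p_sim: dict[str, float] = field(default_factory=dict)
    p_app_exp: float | None = None
    reference: str = ""
    role: str = "training"

    def __post_init__(self) -> None:
        for label, value in self.p_sim.items():
            if not value > 0:
                raise ValueError(f"{self.name}: non-positive P_sim at {label}")
        if self.p_app_exp is not None and not self.p_app_exp > 0:
            raise ValueError(f"{self.name}: non-positive experimental P_app")


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted (or frozen) log10-log10 line with its fit statistics.

    Frozen lines carry ``r_squared``/``p_value`` of None and an empty
    residual table.
    """

    slope: float
    intercept: float  # log10 cm/s
    r_squared: float | None = None
    p_value: float | None = None
    n_points: int = 0
    temperature_label: str = ""
    residuals: Mapping[str, float] = field(default_factory=dict)
    stderr: float | None = None
    intercept_stderr: float | None = None

    def predict_log10(self, log10_p_sim: float | np.ndarray) -> float | np.ndarray:
        return self.slope * log10_p_sim + self.intercept


#: 167 degC calibration at full precision (reproduces the training-table
#: prediction column).
CAL_167C_FULL = CalibrationModel(slope=1.124, intercept=-4.819, temperature_label="167C")
#: the same line rounded to three figures (reproduces the reference-table
#: prediction column).
CAL_167C_ROUNDED = CalibrationModel(slope=1.12, intercept=-4.82, temperature_label="167C")
#: 127 degC calibration.
CAL_127C = CalibrationModel(slope=1.17, intercept=-3.73, temperature_label="127C")

FROZEN_MODELS = {
    "frozen-167C-full": CAL_167C_FULL,
    "frozen-167C-rounded": CAL_167C_ROUNDED,
    "frozen-127C": CAL_127C,
}


def _training_arrays(
    records: Iterable[CompoundRecord], temperature_label: str
) -> tuple[list[str], np.ndarray, np.ndarray]:
    names, x, y = [], [], []
    for rec in records:
        if temperature_label not in rec.p_sim or rec.p_app_exp is None:
            continue
        names.append(rec.name)
        x.append(rec.p_sim[temperature_label])
        y.append(rec.p_app_exp)
    return names, np.asarray(x), np.asarray(y)


def fit_loglog(
    records: Iterable[CompoundRecord], temperature_label: str
) -> CalibrationModel:
    """Ordinary least squares of log10 P_app on log10 P_sim.

    R^2 is the squared Pearson correlation and the p-value the two-sided
    t-test on the slope with n - 2 degrees of freedom (the conventions of
    ``scipy.stats.linregress``, which performs the fit).
    """
    names, x, y = _training_arrays(records, temperature_label)
    if len(names) < 3:
        raise InsufficientDataError(
            f"need >= 3 compounds with P_sim at {temperature_label}, have {len(names)}"
        )
    lx, ly = np.log10(x), np.log10(y)
    res = stats.linregress(lx, ly)
    fitted = res.slope * lx + res.intercept
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=len(names),
        temperature_label=temperature_label,
        residuals=dict(zip(names, (ly - fitted).tolist())),
        stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )


def predict_papp(model: CalibrationModel, p_sim: float | np.ndarray) -> float | np.ndarray:
    """Predicted 37 degC apparent permeability: 10^(m log10 P_sim + c)."""
    p_sim = np.asarray(p_sim, dtype=float)
    if np.any(p_sim <= 0):
        raise ValueError("P_sim must be positive")
    out = 10.0 ** model.predict_log10(np.log10(p_sim))
    return float(out) if out.ndim == 0 else out


def oom_error(p_exp: float, p_pred: float) -> float:
    """Order-of-magnitude error |log10 P_exp - log10 P_pred|."""
    if not (p_exp > 0 and p_pred > 0):
        raise ValueError("permeabilities must be positive")
    return abs(math.log10(p_exp) - math.log10(p_pred))


@dataclass(frozen=True)
class ErrorReport:
    """Per-compound order-of-magnitude errors and their mean.

    ``table`` has one row per compound (name, p_sim, p_exp, p_pred,
    oom_error, kept); ``mean_error`` averages the kept rows only.
    """

    table: pd.DataFrame
    mean_error: float
    trim_gt: float | None


def evaluate_errors(
    inputs: Sequence[tuple[str, float, float]] | pd.DataFrame,
    model: CalibrationModel,
    trim_gt: float | None = None,
) -> ErrorReport:
    """Score a set of (name, P_sim, P_app_exp) triples against a model.

    ``trim_gt`` drops rows whose error exceeds the limit from the mean
    (they stay in the table, flagged ``kept = False``) — used to report a
    trimmed average that is robust to a single badly mispredicted
    compound.
    """
    if isinstance(inputs, pd.DataFrame):
        rows = list(inputs[["name", "p_sim", "p_exp"]].itertuples(index=False))
    else:
        rows = list(inputs)
    if not rows:
        raise EmptyDataError("no compounds to evaluate")
    names = [r[0] for r in rows]
    p_sim = np.asarray([r[1] for r in rows], dtype=float)
    p_exp = np.asarray([r[2] for r in rows], dtype=float)
    p_pred = predict_papp(model, p_sim)
    errors = np.abs(np.log10(p_exp) - np.log10(p_pred))
    kept = np.ones(len(rows), dtype=bool) if trim_gt is None else errors <= trim_gt
    if not kept.any():
        raise EmptyDataError("trim rule removed every compound")
    table = pd.DataFrame(
        {
            "name": names,
            "p_sim": p_sim,
            "p_exp": p_exp,
            "p_pred": p_pred,
            "oom_error": errors,
            "kept": kept,
        }
    )
    return ErrorReport(
        table=table,
        mean_error=float(errors[kept].mean()),
        trim_gt=trim_gt,
    )


@dataclass(frozen=True)
class SubsetStabilityResult:
    """Slope statistics of regressions over all (or sampled) n-subsets."""

    subset_sizes: list[int]
    subset_counts: list[int]        # number of subsets actually fitted
    slope_mean: list[float]
    slope_std: list[float]
    sampling_mode: str              # "exhaustive" | "random(seed=..., cap=...)"


def _vectorized_slopes(lx: np.ndarray, ly: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """OLS slopes for many index subsets at once (normal equations)."""
    xs = lx[idx]
    ys = ly[idx]
    n = idx.shape[1]
    sx = xs.sum(axis=1)
    sy = ys.sum(axis=1)
    sxy = (xs * ys).sum(axis=1)
    sxx = (xs * xs).sum(axis=1)
    return (n * sxy - sx * sy) / (n * sxx - sx * sx)


def subset_stability(
    records: Sequence[CompoundRecord],
    sizes: Sequence[int],
    temperature_label: str = "167C",
    mode: str = "exhaustive",
    seed: int | None = None,
    cap: int = 100_000,
) -> SubsetStabilityResult:
    """Slope variability of the calibration under training-subset size.

    For every requested subset size n, fits a log-log OLS line to each
    n-compound subset of the training library and records the mean and
    standard deviation of the slopes.  ``exhaustive`` mode enumerates all
    C(N, n) subsets (refusing beyond *cap*); ``random`` mode draws
    min(cap, C(N, n)) subsets with a seeded generator.

    A slope-vs-n curve that plateaus indicates the library is large
    enough that the calibration no longer depends on which compounds were
    included.
    """
    names, x, y = _training_arrays(records, temperature_label)
    n_total = len(names)
    lx, ly = np.log10(x), np.log10(y)
    rng = np.random.default_rng(seed)
    counts, means, stds = [], [], []
    for n in sizes:
        if n < 3:
            raise InsufficientDataError(f"subset size {n} < 3 cannot be fitted")
        if n > n_total:
            raise InsufficientDataError(f"subset size {n} exceeds library size {n_total}")
        n_combos = math.comb(n_total, n)
        if mode == "exhaustive":
            if n_combos > cap:
                raise InsufficientDataError(
                    f"C({n_total}, {n}) = {n_combos} subsets exceeds cap = {cap}; "
                    "use mode='random'"
                )
            idx = np.fromiter(
                itertools.chain.from_iterable(itertools.combinations(range(n_total), n)),
                dtype=np.int64,
            ).reshape(n_combos, n)
        elif mode == "random":
            n_draw = min(cap, n_combos)
            idx = np.stack(
                [rng.choice(n_total, size=n, replace=False) for _ in range(n_draw)]
            )
        else:
            raise ValueError(f"unknown sampling mode: {mode!r}")
        slopes = _vectorized_slopes(lx, ly, idx)
        counts.append(idx.shape[0])
        means.append(float(slopes.mean()))
        stds.append(float(slopes.std(ddof=0)))
    label = "exhaustive" if mode == "exhaustive" else f"random(seed={seed}, cap={cap})"
    return SubsetStabilityResult(
        subset_sizes=list(sizes),
        subset_counts=counts,
        slope_mean=means,
        slope_std=stds,
        sampling_mode=label,
    )


@dataclass(frozen=True)
class RankedCompound:
    name: str
    p_app_pred: float
    tied: bool


def rank_compounds(predictions: Mapping[str, float]) -> list[RankedCompound]:
    """Order compounds by predicted apparent permeability, descending.

    Ties are broken alphabetically and flagged.  Because every fitted
    calibration has a positive slope, this order coincides with the order
    of the underlying P_sim values — the method is a *ranking* tool.
    """
    if not predictions:
        raise EmptyDataError("no predictions to rank")
    for name, value in predictions.items():
        if not value > 0:
            raise ValueError(f"{name}: predictions must be positive")
    ordered = sorted(predictions.items(), key=lambda kv: (-kv[1], kv[0]))
    values = [v for _, v in ordered]
    out = []
    for i, (name, value) in enumerate(ordered):
        tied = (i > 0 and values[i - 1] == value) or (
            i + 1 < len(values) and values[i + 1] == value
        )
        out.append(RankedCompound(name=name, p_app_pred=value, tied=tied))
    return out
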