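"""End-to-end run: z-series in, ranked 37 degC prediction out.

Chains load -> recentre -> detect -> rate -> steady state -> P_sim ->
calibrated P_app prediction, recording every parameter and seed so a run
is reproducible from its log.  Each stage failure is re-raised as a
:class:`~tbcperm.errors.StageError` naming the stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import calib, datasets, kinetics, tbc, trajio
from .errors import StageError, TbcpermError

__all__ = ["RunConfig", "PipelineReport", "run_pipeline"]

_CALIBRATION_CHOICES = (
    "frozen-167C-full",
    "frozen-167C-rounded",
    "frozen-127C",
    "fit-167C",
    "fit-127C",
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``concentration_C`` (mol/cm^3) defaults to the series' own solute
    count in the box volume ``area_A * box_z``; ``area_A`` defaults to
    the 25 nm^2 lateral area of the standard bilayer patch.
    """

    input_path: str
    checkpoint_interval: float = 10.0   # ns
    threshold: float = 0.004            # ns^-2
    min_plateau_checkpoints: int = 5
    crossing_offset: float = 1.0        # nm
    area_A: float = 25.0                # nm^2
    concentration_C: float | None = None  # mol/cm^3
    calibration: str = "frozen-167C-full"
    sigma_method: str = "poisson"
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "checkpoint_interval",
            "threshold",
            "crossing_offset",
            "area_A",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.concentration_C is not None and not self.concentration_C > 0:
            raise ValueError("concentration_C must be positive")
        if self.calibration not in _CALIBRATION_CHOICES:
            raise ValueError(
                f"calibration must be one of {_CALIBRATION_CHOICES}, "
                f"got {self.calibration!r}"
            )


@dataclass
class PipelineReport:
    label: str
    n_events: int
    estimate: kinetics.PermeabilityEstimate
    model: calib.CalibrationModel
    p_app_pred: float
    config: dict = field(default_factory=dict)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def _resolve_model(choice: str) -> calib.CalibrationModel:
    if choice in calib.FROZEN_MODELS:
        return calib.FROZEN_MODELS[choice]
    label = choice.removeprefix("fit-")
    return calib.fit_loglog(datasets.load_compound_records(), label)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the whole chain on one z-series text file."""
    with _stage("load"):
        series = trajio.read_zseries_text(config.input_path)

    with _stage("geometry"):
        geom = tbc.estimate_membrane_geometry(
            series, crossing_offset=config.crossing_offset
        )

    with _stage("recentre"):
        series = trajio.recentre_and_wrap(series, geom.midplane)
        geom = tbc.MembraneGeometry(
            geom.lower_boundary - geom.midplane,
            geom.upper_boundary - geom.midplane,
            geom.crossing_offset,
        )

    with _stage("detect"):
        events = tbc.detect_crossings(series, geom)

    with _stage("rate"):
        rates = tbc.rate_series(
            events, series.total_time, config.checkpoint_interval
        )

    with _stage("steady_state"):
        concentration = config.concentration_C
        if concentration is None:
            volume = config.area_A * series.constant_box_z()
            concentration = kinetics.molar_concentration(series.n_solutes, volume)
        estimate = kinetics.permeability_estimate(
            rates,
            area_A=config.area_A,
            concentration_C=concentration,
            temperature=series.temperature,
            threshold=config.threshold,
            min_plateau_checkpoints=config.min_plateau_checkpoints,
            sigma_method=config.sigma_method,
        )

    with _stage("predict"):
        model = _resolve_model(config.calibration)
        p_app = calib.predict_papp(model, estimate.P_sim)

    report = PipelineReport(
        label=series.label,
        n_events=len(events),
        estimate=estimate,
        model=model,
        p_app_pred=p_app,
        config=asdict(config),
    )
    if config.output_dir is not None:
        _write_outputs(report, events, config)
    return report


def _write_outputs(
    report: PipelineReport, events: list[tbc.CrossingEvent], config: RunConfig
) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tbc.events_table(events).to_csv(outdir / "events.tsv", sep="\t", index=False)
    est = report.estimate
    with (outdir / "estimate.tsv").open("w") as fh:
        fh.write(
            "compound\tT_K\tk_ss_ns\tk_sigma_ns\tP_sim_cm_s\tP_sigma_cm_s\t"
            "P_app_pred_cm_s\n"
        )
        fh.write(
            f"{report.label}\t{est.temperature:g}\t{est.k_ss:.6g}\t"
            f"{est.k_sigma:.6g}\t{est.P_sim:.6g}\t{est.P_sigma:.6g}\t"
            f"{report.p_app_pred:.6g}\n"
        )
    log = {
        "config": report.config,
        "model": {
            "slope": report.model.slope,
            "intercept": report.model.intercept,
            "temperature_label": report.model.temperature_label,
        },
        "n_events": report.n_events,
        "plateau_onset_ns": est.plateau_onset,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")


def is_input_error(exc: Exception) -> bool:
    """Classify an error for exit-code purposes (input vs convergence)."""
    from .errors import NonConvergenceError

    if isinstance(exc, StageError):
        return is_input_error(exc.cause)
    return isinstance(exc, (TbcpermError, ValueError, OSError)) and not isinstance(
        exc, NonConvergenceError
    )
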