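"""End-to-end pipeline: events -> triggered averages -> filters ->
nonlinearity fits -> predictions, with provenance-stamped artifacts."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__, io
from .errors import OptorcError, PipelineError
from .events import RUN_TO_TURN, TURN_TO_RUN, extract_transitions
from .lnmodel import LNModel, estimate_nonlinearity, linear_predict, predict_response
from .revcorr import filter_from_ta, triggered_average

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    stim_path: str
    tracks_path: str
    out_dir: str
    window: float = 4.0
    trial_duration: float = 1200.0
    n_bins: int = 20
    alpha: float = 0.05
    seed: int = 0
    form_rt: str = "sigmoid"
    form_tr: str = "linear"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.trial_duration <= 0:
            raise PipelineError("config: durations must be positive")
        if not 0 < self.alpha < 1:
            raise PipelineError("config: alpha must lie in (0, 1)")

    def digest(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis on the same data hashes identically anywhere)."""
        params = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("stim_path", "tracks_path", "out_dir")
        }
        return hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except OptorcError as exc:
                raise PipelineError(f"{name}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute events -> revcorr -> nonlinearity fit -> predict and write
    every artifact under ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json``).  Any
    stage failure raises :class:`PipelineError` naming the stage; the
    report written so far is marked incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "version": __version__,
        "complete": False,
        "stages": {},
    }
    try:
        stim, tracks = _load(config)
        report["stages"]["load"] = {
            "n_stimulus_samples": stim.n_samples,
            "n_tracks": len(tracks),
        }
        events = _events(config, tracks, out)
        report["stages"]["events"] = {"n_events": len(events)}
        model, revcorr_info = _revcorr_and_fit(config, stim, tracks, events, out)
        report["stages"]["revcorr"] = revcorr_info
        pred_info = _predict(model, stim, out)
        report["stages"]["predict"] = pred_info
        report["complete"] = True
    finally:
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


@_stage("load")
def _load(config: RunConfig):
    stim = io.read_stimulus(config.stim_path)
    tracks = io.read_tracks(config.tracks_path)
    if not tracks:
        raise PipelineError("load: no tracks found")
    for tr in tracks:
        if not math.isclose(tr.dt, stim.dt, rel_tol=1e-9):
            raise PipelineError(
                f"load: track {tr.animal_id} dt ({tr.dt}) does not match "
                f"stimulus dt ({stim.dt})"
            )
    return stim, tracks


@_stage("events")
def _events(config: RunConfig, tracks, out: Path):
    events = []
    for tr in tracks:
        events.extend(extract_transitions(tr))
    io.write_events(events, out / "events.csv")
    logger.info("events: %d transitions from %d tracks", len(events), len(tracks))
    return events


@_stage("revcorr")
def _revcorr_and_fit(config: RunConfig, stim, tracks, events, out: Path):
    info = {}
    filters, nonlins = {}, {}
    n_trials = len(tracks)
    for kind, tag, form in (
        (RUN_TO_TURN, "rt", config.form_rt),
        (TURN_TO_RUN, "tr", config.form_tr),
    ):
        ta = triggered_average(events, stim, kind, window=config.window)
        io.write_triggered_average(ta, out / f"ta_{tag}.csv")
        mean_per_trial = ta.n_events / n_trials
        filt = filter_from_ta(ta, mean_per_trial, config.trial_duration)
        io.write_filter(
            filt, out / f"filter_{tag}.json",
            provenance={"n_events": ta.n_events, "n_excluded": ta.n_excluded,
                        "window": config.window},
        )
        drive = linear_predict(filt, stim)
        nonlin = estimate_nonlinearity(drive, tracks, kind, n_bins=config.n_bins, form=form)
        filters[kind] = filt
        nonlins[kind] = nonlin
        info[tag] = {
            "n_events": ta.n_events,
            "n_excluded": ta.n_excluded,
            "form": nonlin.form,
            "r_squared": nonlin.goodness,
        }
        logger.info(
            "revcorr[%s]: %d events (%d excluded), %s fit R^2 = %.4f",
            kind, ta.n_events, ta.n_excluded, nonlin.form, nonlin.goodness,
        )
    model = LNModel(
        filter_rt=filters[RUN_TO_TURN],
        filter_tr=filters[TURN_TO_RUN],
        nonlin_rt=nonlins[RUN_TO_TURN],
        nonlin_tr=nonlins[TURN_TO_RUN],
        provenance={
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "window": config.window,
            "trial_duration": config.trial_duration,
        },
    )
    io.write_model(model, out / "model.json")
    return model, info


@_stage("predict")
def _predict(model: LNModel, stim, out: Path):
    predictions = predict_response(model, stim)
    io.write_psth_table(out / "predictions.csv", predicted=predictions)
    return {
        kind: {"n_bins": int(tr.p.size), "n_burnin": tr.n_burnin}
        for kind, tr in predictions.items()
    }
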