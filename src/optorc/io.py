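"""Plain-text serialization: CSV for time series and tables, JSON for
fitted models.  All writers round-trip losslessly through the matching
readers."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .events import TransitionEvent
from .lnmodel import EmpiricalPSTH, LNModel, PredictionTrace, StaticNonlinearity
from .revcorr import LinearFilter, TriggeredAverage
from .stats import SignificanceTrace
from .stimulus import StimulusTrain
from .tracks import StateTrack

logger = logging.getLogger(__name__)

__all__ = [
    "read_stimulus", "write_stimulus",
    "read_tracks", "write_tracks",
    "read_events", "write_events",
    "read_triggered_average", "write_triggered_average",
    "read_filter", "write_filter",
    "read_model", "write_model",
    "write_psth_table", "read_psth_table",
    "write_significance", "read_significance",
]


# -- stimulus -----------------------------------------------------------------

def write_stimulus(stim: StimulusTrain, path) -> None:
    df = pd.DataFrame({"time_s": stim.times, "value": stim.values})
    df.to_csv(path, index=False)


def read_stimulus(path) -> StimulusTrain:
    """Read a `time_s, value` CSV.  Values may be coded -1/+1 or 0/1;
    0/1 input is recoded to the canonical -1/+1 with a log notice."""
    df = pd.read_csv(path)
    if not {"time_s", "value"}.issubset(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns time_s, value")
    values = df["value"].to_numpy()
    if set(np.unique(values)) <= {0, 1}:
        logger.info("%s: recoding 0/1 stimulus values to -1/+1", path)
        values = np.where(values > 0, 1, -1)
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise InvalidArgumentError(f"{path}: need at least 2 samples to infer dt")
    dt = float(np.median(np.diff(times)))
    if not np.allclose(np.diff(times), dt, atol=1e-9):
        raise InvalidArgumentError(f"{path}: sample times are not uniform")
    return StimulusTrain(t0=float(times[0]), dt=dt, values=values)


# -- tracks -------------------------------------------------------------------

def write_tracks(tracks: list[StateTrack], path) -> None:
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": tr.animal_id,
                    "time_s": tr.times,
                    "state": tr.state_labels,
                    "speed": tr.speed if tr.speed is not None else np.nan,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path) -> list[StateTrack]:
    df = pd.read_csv(path)
    required = {"animal_id", "time_s", "state"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns {sorted(required)}")
    tracks = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if times.size < 2:
            raise InvalidArgumentError(f"{path}: track {animal_id} has fewer than 2 samples")
        dt = float(np.median(np.diff(times)))
        if not np.allclose(np.diff(times), dt, atol=1e-9):
            raise InvalidArgumentError(f"{path}: track {animal_id} is not uniformly sampled")
        speed = None
        if "speed" in grp.columns and not grp["speed"].isna().all():
            speed = grp["speed"].to_numpy(dtype=float)
        tracks.append(
            StateTrack(
                animal_id=str(animal_id),
                t0=float(times[0]),
                dt=dt,
                states=grp["state"].to_numpy(),
                speed=speed,
            )
        )
    return tracks


# -- events -------------------------------------------------------------------

def write_events(events: list[TransitionEvent], path) -> None:
    pd.DataFrame(
        {
            "animal_id": [e.animal_id for e in events],
            "time_s": [e.time for e in events],
            "kind": [e.kind for e in events],
        }
    ).to_csv(path, index=False)


def read_events(path) -> list[TransitionEvent]:
    df = pd.read_csv(path)
    if not {"animal_id", "time_s", "kind"}.issubset(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns animal_id, time_s, kind")
    return [
        TransitionEvent(str(r.animal_id), float(r.time_s), str(r.kind))
        for r in df.itertuples()
    ]


# -- triggered averages and filters ------------------------------------------

def write_triggered_average(ta: TriggeredAverage, path) -> None:
    pd.DataFrame(
        {
            "lag_s": ta.lags,
            "mean": ta.mean,
            "sem": ta.sem,
            "sd": ta.sd,
            "n_events": ta.n_events,
            "kind": ta.kind,
        }
    ).to_csv(path, index=False)


def read_triggered_average(path) -> TriggeredAverage:
    df = pd.read_csv(path)
    required = {"lag_s", "mean", "sem", "n_events", "kind"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns {sorted(required)}")
    n = int(df["n_events"].iloc[0])
    sem = df["sem"].to_numpy(dtype=float)
    sd = df["sd"].to_numpy(dtype=float) if "sd" in df.columns else sem * np.sqrt(n)
    return TriggeredAverage(
        lags=df["lag_s"].to_numpy(dtype=float),
        mean=df["mean"].to_numpy(dtype=float),
        sem=sem,
        sd=sd,
        n_events=n,
        kind=str(df["kind"].iloc[0]),
    )


def _filter_to_dict(filt: LinearFilter) -> dict:
    return {
        "taus": filt.taus.tolist(),
        "h": filt.h.tolist(),
        "dt": filt.dt,
        "kind": filt.kind,
    }


def _filter_from_dict(d: dict) -> LinearFilter:
    return LinearFilter(
        taus=np.asarray(d["taus"], dtype=float),
        h=np.asarray(d["h"], dtype=float),
        dt=float(d["dt"]),
        kind=str(d["kind"]),
    )


def write_filter(filt: LinearFilter, path, provenance: dict | None = None) -> None:
    payload = _filter_to_dict(filt)
    payload["provenance"] = provenance or {}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_filter(path) -> LinearFilter:
    return _filter_from_dict(json.loads(Path(path).read_text()))


# -- models -------------------------------------------------------------------

def _nonlin_to_dict(nl: StaticNonlinearity | None):
    if nl is None:
        return None
    return {"form": nl.form, "params": nl.params, "goodness": nl.goodness}


def _nonlin_from_dict(d) -> StaticNonlinearity | None:
    if d is None:
        return None
    return StaticNonlinearity(d["form"], d["params"], goodness=d.get("goodness"))


def write_model(model: LNModel, path) -> None:
    payload = {
        "filter_rt": _filter_to_dict(model.filter_rt) if model.filter_rt else None,
        "filter_tr": _filter_to_dict(model.filter_tr) if model.filter_tr else None,
        "nonlin_rt": _nonlin_to_dict(model.nonlin_rt),
        "nonlin_tr": _nonlin_to_dict(model.nonlin_tr),
        "provenance": model.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model(path) -> LNModel:
    d = json.loads(Path(path).read_text())
    return LNModel(
        filter_rt=_filter_from_dict(d["filter_rt"]) if d.get("filter_rt") else None,
        filter_tr=_filter_from_dict(d["filter_tr"]) if d.get("filter_tr") else None,
        nonlin_rt=_nonlin_from_dict(d.get("nonlin_rt")),
        nonlin_tr=_nonlin_from_dict(d.get("nonlin_tr")),
        provenance=d.get("provenance", {}),
    )


# -- PSTH / prediction tables -------------------------------------------------

def write_psth_table(
    path,
    predicted: dict[str, PredictionTrace] | None = None,
    observed: dict[str, EmpiricalPSTH] | None = None,
) -> None:
    """`time_s, p, n, kind, source` table pooling predicted and observed
    traces; predicted rows have n = 0."""
    frames = []
    for kind, trace in (predicted or {}).items():
        frames.append(
            pd.DataFrame(
                {"time_s": trace.times, "p": trace.p, "n": 0, "kind": kind,
                 "source": "predicted"}
            )
        )
    for kind, psth in (observed or {}).items():
        frames.append(
            pd.DataFrame(
                {"time_s": psth.times, "p": psth.p, "n": psth.n, "kind": kind,
                 "source": "observed"}
            )
        )
    if not frames:
        raise InvalidArgumentError("nothing to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_psth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_s", "p", "n", "kind", "source"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns {sorted(required)}")
    return df


# -- significance -------------------------------------------------------------

def write_significance(trace: SignificanceTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s_or_lag_s": trace.times,
            "p_value": trace.p_values,
            "valid": trace.valid,
            "significant": trace.significant,
        }
    ).to_csv(path, index=False)


def read_significance(path, alpha: float = 0.05) -> SignificanceTrace:
    df = pd.read_csv(path)
    required = {"time_s_or_lag_s", "p_value", "valid"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"{path}: expected columns {sorted(required)}")
    return SignificanceTrace(
        times=df["time_s_or_lag_s"].to_numpy(dtype=float),
        p_values=df["p_value"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
        alpha=alpha,
    )
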