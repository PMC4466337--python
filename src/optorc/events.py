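"""Transition-event extraction and speed analysis.

Events are timestamped at the first sample of the new state.  Speed
normalization uses the standard score relative to the same animal's
RUN-state speed (population standard deviation, i.e. divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, InvalidArgumentError, NotFoundError
from .tracks import RUN, TURN, StateTrack

__all__ = [
    "RUN_TO_TURN",
    "TURN_TO_RUN",
    "TransitionEvent",
    "extract_transitions",
    "normalize_speed",
    "deceleration_onset",
]

RUN_TO_TURN = "RUN_TO_TURN"
TURN_TO_RUN = "TURN_TO_RUN"

_KINDS = (RUN_TO_TURN, TURN_TO_RUN)


@dataclass(frozen=True)
class TransitionEvent:
    """One motor-state transition, timed at the first sample of the new
    state."""

    animal_id: str
    time: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidArgumentError(f"unknown transition kind {self.kind!r}")


def extract_transitions(track: StateTrack) -> list[TransitionEvent]:
    """One event per state change; alternation in kind is guaranteed by
    construction since the states are binary."""
    codes = track.states
    change = np.flatnonzero(np.diff(codes) != 0) + 1
    events = []
    for i in change:
        kind = RUN_TO_TURN if codes[i] == 1 else TURN_TO_RUN
        events.append(TransitionEvent(track.animal_id, track.t0 + i * track.dt, kind))
    return events


def normalize_speed(track: StateTrack) -> np.ndarray:
    """Standard-score the speed trace against the animal's RUN-state speed.

    Returns ``(speed - mean_run) / sd_run`` where the statistics are taken
    over RUN samples only and the standard deviation is the population one
    (divide by n).
    """
    if track.speed is None:
        raise InvalidArgumentError("track has no speed trace")
    run_mask = track.states == 0
    if run_mask.sum() < 2:
        raise InvalidArgumentError("need at least 2 RUN samples to normalize speed")
    run_speed = track.speed[run_mask]
    mu = run_speed.mean()
    sd = run_speed.std(ddof=0)
    if sd == 0.0:
        raise DegenerateDataError("RUN-state speed has zero variance")
    return (track.speed - mu) / sd


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; for even widths the window covers
    ``[i - w//2, i + w//2 - 1]`` (ties toward earlier samples).  Edges are
    padded by repeating the end values."""
    if width <= 1:
        return values.astype(np.float64)
    left = width // 2
    right = width - 1 - left
    padded = np.pad(values.astype(np.float64), (left, right), mode="edge")
    kernel = np.full(width, 1.0 / width)
    return np.convolve(padded, kernel, mode="valid")


def deceleration_onset(
    track: StateTrack,
    event,
    window: float = 2.0,
    smooth: float = 0.5,
) -> float:
    """Time (seconds, <= 0, relative to the event) at which the run began
    to slow before a run-to-turn transition.

    The speed trace is smoothed with a centered moving average of width
    ``smooth``; the onset is the last sample before the final sign change
    of the first-difference derivative from >= 0 to < 0 within ``window``
    that is followed by monotone non-increase of the smoothed speed up to
    the event.

    Raises
    ------
    NotFoundError
        If no such deceleration epoch exists in the window.
    """
    if event.kind != RUN_TO_TURN:
        raise InvalidArgumentError("deceleration onset is defined for RUN_TO_TURN events")
    if track.speed is None:
        raise InvalidArgumentError("track has no speed trace")
    if window <= 0:
        raise InvalidArgumentError("window must be positive")
    e = int(round((event.time - track.t0) / track.dt))
    if e < 1 or e >= track.n_samples:
        raise InvalidArgumentError("event does not lie on the track's sample grid")
    w_n = int(round(window / track.dt))
    if e - w_n < 0:
        raise InvalidArgumentError("insufficient speed history before the event")
    width = int(round(smooth / track.dt))
    smoothed = _smooth(track.speed, width)
    d = np.diff(smoothed)  # d[i] = s[i+1] - s[i]
    onset_idx = None
    # candidate k: first decreasing sample of a monotone non-increasing
    # stretch reaching the event; scan for the last such sign change
    for k in range(e, e - w_n, -1):
        if d[k - 1] < 0 and (k - 1 == 0 or d[k - 2] >= 0):
            if np.all(d[k - 1 : e] <= 0):
                onset_idx = k - 1
                break
    if onset_idx is None:
        raise NotFoundError("no deceleration onset found in the window")
    return (onset_idx - e) * track.dt
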