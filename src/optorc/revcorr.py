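"""Event-triggered stimulus averages and the linear filters derived from them.

The estimator is the classic reverse-correlation one: average the +/-1
stimulus history preceding each motor-state transition (the
event-triggered average C(tau), reported over lags -W..0), then rescale
by the mean event rate — the average number of events per trial divided
by the trial duration — to obtain the causal linear filter h(tau).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyResultError, InvalidArgumentError
from .events import RUN_TO_TURN, TURN_TO_RUN, TransitionEvent
from .stimulus import StimulusTrain

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_TRIAL_DURATION",
    "TriggeredAverage",
    "LinearFilter",
    "triggered_average",
    "filter_from_ta",
]

#: Default stimulus-history window in seconds.  Turns rarely last longer
#: than ~4 s, which bounds the usable history length.
DEFAULT_WINDOW = 4.0

#: Default trial duration in seconds (20-minute trials).
DEFAULT_TRIAL_DURATION = 1200.0


@dataclass(frozen=True)
class TriggeredAverage:
    """Mean +/- SEM stimulus history preceding one transition type.

    ``lags`` run from ``-window`` to 0 in steps of ``dt``; lag 0 is the
    stimulus sample containing the event time.  ``sd`` (per-lag sample
    standard deviation over events) is retained so that two averages can
    later be compared with per-lag t-tests.  ``n_excluded`` counts events
    dropped because their history window ran off the start of the
    stimulus.
    """

    lags: np.ndarray = field(repr=False)
    mean: np.ndarray = field(repr=False)
    sem: np.ndarray = field(repr=False)
    sd: np.ndarray = field(repr=False)
    n_events: int
    kind: str
    n_excluded: int = 0

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        mean = np.asarray(self.mean, dtype=float)
        sem = np.asarray(self.sem, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if not (lags.shape == mean.shape == sem.shape == sd.shape):
            raise InvalidArgumentError("lags, mean, sem and sd must have equal shapes")
        if np.any(np.abs(mean) > 1 + 1e-12):
            raise InvalidArgumentError("triggered-average means must lie in [-1, 1]")
        if np.any(sem < 0):
            raise InvalidArgumentError("sem must be nonnegative")
        if self.kind not in (RUN_TO_TURN, TURN_TO_RUN):
            raise InvalidArgumentError(f"unknown transition kind {self.kind!r}")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sem", sem)
        object.__setattr__(self, "sd", sd)

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if self.lags.size > 1 else 0.0

    @property
    def window(self) -> float:
        return float(-self.lags[0])


@dataclass(frozen=True)
class LinearFilter:
    """Causal discrete kernel h(tau) for one transition type.

    ``h`` has units of rate contribution per unit stimulus per second;
    convolving it with a +/-1 stimulus (times dt) yields a linearly
    predicted transition rate in events/s.
    """

    taus: np.ndarray = field(repr=False)
    h: np.ndarray = field(repr=False)
    dt: float
    kind: str = RUN_TO_TURN

    def __post_init__(self) -> None:
        taus = np.asarray(self.taus, dtype=float)
        h = np.asarray(self.h, dtype=float)
        if taus.shape != h.shape or taus.ndim != 1 or taus.size < 1:
            raise InvalidArgumentError("taus and h must be equal-length 1-D sequences")
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if taus[0] < -1e-12:
            raise InvalidArgumentError("filter must be causal (taus >= 0)")
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "h", h)

    @property
    def n_taps(self) -> int:
        return int(self.h.size)

    @property
    def support(self) -> float:
        """Length of the kernel support in seconds."""
        return self.n_taps * self.dt


def _usable_event_indices(
    events: list[TransitionEvent], stim: StimulusTrain, kind: str, n_lags: int
) -> tuple[np.ndarray, int]:
    """Sample indices of usable events of the given kind, plus the count
    of events excluded for incomplete history."""
    idx = []
    n_excluded = 0
    for ev in events:
        if ev.kind != kind:
            continue
        k = stim.index_at(ev.time)
        if k >= stim.n_samples:
            n_excluded += 1
            continue
        if k - (n_lags - 1) < 0:
            n_excluded += 1
            continue
        idx.append(k)
    return np.asarray(idx, dtype=np.intp), n_excluded


def triggered_average(
    events: list[TransitionEvent],
    stim: StimulusTrain,
    kind: str,
    window: float = DEFAULT_WINDOW,
) -> TriggeredAverage:
    """Average the stimulus history preceding each event of ``kind``.

    For every usable event at time t_e, the stimulus samples at
    ``t_e + lag`` for lag in ``-window .. 0`` are collected; the mean,
    per-lag sample standard deviation and standard error over events are
    returned.  Events whose window reaches before the start of the
    stimulus are excluded and counted in ``n_excluded``.

    Raises
    ------
    EmptyResultError
        If no usable event remains.
    """
    if window <= 0:
        raise InvalidArgumentError("window must be positive")
    if window > stim.duration:
        raise InvalidArgumentError("window must not exceed the stimulus duration")
    n_lags = int(round(window / stim.dt)) + 1
    idx, n_excluded = _usable_event_indices(events, stim, kind, n_lags)
    n = idx.size
    if n == 0:
        raise EmptyResultError(f"no usable {kind} events (excluded {n_excluded})")
    offsets = np.arange(-(n_lags - 1), 1)
    gathered = stim.values[idx[:, None] + offsets[None, :]].astype(np.float64)
    mean = gathered.mean(axis=0)
    if n >= 2:
        sd = gathered.std(axis=0, ddof=1)
    else:
        sd = np.zeros(n_lags)
    sem = sd / np.sqrt(n)
    lags = stim.dt * offsets.astype(float)
    return TriggeredAverage(
        lags=lags, mean=mean, sem=sem, sd=sd, n_events=int(n), kind=kind, n_excluded=n_excluded
    )


def filter_from_ta(
    ta: TriggeredAverage,
    mean_events_per_trial: float,
    trial_duration: float = DEFAULT_TRIAL_DURATION,
) -> LinearFilter:
    """Convert a triggered average into a causal linear filter.

    ``h(tau) = (<n> / T) * C(-tau)`` where ``<n>`` is the mean number of
    events per trial and ``T`` the trial duration; the lag axis is
    reversed so that ``tau >= 0`` reads backwards into stimulus history.
    """
    if trial_duration <= 0:
        raise InvalidArgumentError("trial_duration must be positive")
    if mean_events_per_trial < 0:
        raise InvalidArgumentError("mean_events_per_trial must be nonnegative")
    scale = mean_events_per_trial / trial_duration
    taus = -ta.lags[::-1]
    h = scale * ta.mean[::-1]
    dt = ta.dt if ta.dt > 0 else 1.0
    return LinearFilter(taus=taus, h=h, dt=dt, kind=ta.kind)
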