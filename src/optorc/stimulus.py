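"""Binary (+/-1) stimulus waveforms on a uniform clock.

The canonical internal coding is -1 (lights OFF) / +1 (lights ON); file
readers accept 0/1 and recode with a log notice.  The default sample
interval is 0.25 s (a 4 Hz stimulus/acquisition clock).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, InvalidArgumentError

__all__ = [
    "DEFAULT_DT",
    "StimulusTrain",
    "generate_bernoulli",
    "make_step",
    "make_pulse_train",
    "autocorrelation",
]

logger = logging.getLogger(__name__)

#: Default sample interval in seconds (4 Hz clock).
DEFAULT_DT = 0.25


@dataclass(frozen=True)
class StimulusTrain:
    """A uniformly sampled +/-1 light sequence.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sample interval, seconds; must be positive.
    values : numpy.ndarray
        One-dimensional array whose entries are exactly -1 or +1.
    """

    t0: float
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        if values.ndim != 1 or values.size < 1:
            raise InvalidArgumentError("values must be a non-empty 1-D sequence")
        if self.dt <= 0:
            raise InvalidArgumentError(f"dt must be positive, got {self.dt}")
        if not np.isin(values, (-1, 1)).all():
            bad = np.unique(values[~np.isin(values, (-1, 1))])
            raise InvalidArgumentError(f"stimulus values must be -1 or +1, found {bad.tolist()}")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Total covered time, ``n_samples * dt`` seconds."""
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + k*dt``."""
        return self.t0 + self.dt * np.arange(self.n_samples)

    def index_at(self, time: float) -> int:
        """Index of the sample whose bin contains ``time`` (nearest grid
        point, half-sample ties toward the earlier sample)."""
        return snap_to_grid(time - self.t0, self.dt)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_samples


def snap_to_grid(time: float, dt: float) -> int:
    """Snap a time offset to the nearest sample index, ties going to the
    earlier sample (round-half-down)."""
    return int(np.ceil(time / dt - 0.5))


def generate_bernoulli(
    duration: float,
    dt: float = DEFAULT_DT,
    p_on: float = 0.5,
    seed: int | None = None,
) -> StimulusTrain:
    """Generate a Bernoulli +/-1 white-noise train.

    Each sample is independently +1 with probability ``p_on`` and -1
    otherwise.  With ``p_on = 0.5`` the sequence is zero-mean white noise
    whose autocorrelation is a discrete delta, which is what makes the
    event-triggered average an unbiased estimate of the linear filter.

    Parameters
    ----------
    duration : float
        Length of the train in seconds; the number of samples is
        ``round(duration / dt)``.
    dt : float
        Sample interval in seconds (default 0.25, i.e. 4 Hz).
    p_on : float
        Probability of the ON (+1) state per sample.
    seed : int or None
        Seed for :func:`numpy.random.default_rng`; identical seeds give
        identical trains.
    """
    if duration <= 0:
        raise InvalidArgumentError(f"duration must be positive, got {duration}")
    if dt <= 0:
        raise InvalidArgumentError(f"dt must be positive, got {dt}")
    if not 0.0 <= p_on <= 1.0:
        raise InvalidArgumentError(f"p_on must be in [0, 1], got {p_on}")
    n = int(round(duration / dt))
    if n < 1:
        raise InvalidArgumentError("duration shorter than one sample interval")
    rng = np.random.default_rng(seed)
    values = np.where(rng.random(n) < p_on, 1, -1).astype(np.int8)
    return StimulusTrain(t0=0.0, dt=dt, values=values)


def make_step(
    duration: float,
    dt: float = DEFAULT_DT,
    switch_times: list[float] | None = None,
    initial: int = -1,
) -> StimulusTrain:
    """Build a piecewise-constant +/-1 train toggling at given times.

    Switch times are snapped to the nearest sample boundary with
    half-sample ties toward the earlier sample.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    if initial not in (-1, 1):
        raise InvalidArgumentError(f"initial must be -1 or +1, got {initial}")
    switch_times = list(switch_times or [])
    if any(t2 <= t1 for t1, t2 in zip(switch_times, switch_times[1:])):
        raise InvalidArgumentError("switch times must be strictly increasing")
    if any(t < 0 or t >= duration for t in switch_times):
        raise InvalidArgumentError("switch times must lie in [0, duration)")
    n = int(round(duration / dt))
    values = np.full(n, initial, dtype=np.int8)
    level = initial
    indices = [max(0, snap_to_grid(t, dt)) for t in switch_times]
    for idx in indices:
        level = -level
        values[idx:] = level
    return StimulusTrain(t0=0.0, dt=dt, values=values)


def make_pulse_train(
    duration: float,
    dt: float = DEFAULT_DT,
    pulse_widths: list[float] = (),
    gaps: list[float] = (),
) -> StimulusTrain:
    """Build an alternating sequence of +1 pulses separated by -1 gaps.

    Pulses start at ``t0``; ``gaps[i]`` follows ``pulse_widths[i]``.  Any
    remaining duration after the last pulse is -1.
    """
    if duration <= 0 or dt <= 0:
        raise InvalidArgumentError("duration and dt must be positive")
    pulse_widths = list(pulse_widths)
    gaps = list(gaps)
    if any(w <= 0 for w in pulse_widths) or any(g <= 0 for g in gaps):
        raise InvalidArgumentError("pulse widths and gaps must be positive")
    if len(gaps) > max(len(pulse_widths) - 1, 0):
        raise InvalidArgumentError("at most len(pulse_widths) - 1 gaps are allowed")
    total = sum(pulse_widths) + sum(gaps)
    if total > duration + 1e-9:
        raise InvalidArgumentError(
            f"pulses and gaps span {total} s which exceeds the {duration} s duration"
        )
    n = int(round(duration / dt))
    values = np.full(n, -1, dtype=np.int8)
    t = 0.0
    for i, width in enumerate(pulse_widths):
        start = snap_to_grid(t, dt)
        stop = snap_to_grid(t + width, dt)
        values[start:stop] = 1
        t += width
        if i < len(gaps):
            t += gaps[i]
    return StimulusTrain(t0=0.0, dt=dt, values=values)


def autocorrelation(train: StimulusTrain, max_lag: float) -> np.ndarray:
    """Biased sample autocorrelation of the mean-removed train.

    Returns a structured-friendly ``(n_lags, 2)`` array of
    ``(lag_seconds, value)`` rows for lags ``0, dt, ..., max_lag``,
    normalized so the value at lag 0 is exactly 1.

    Raises
    ------
    DegenerateDataError
        If the train has zero variance (e.g. constant +1).
    InvalidArgumentError
        If ``max_lag`` is not shorter than the train duration.
    """
    if max_lag >= train.duration:
        raise InvalidArgumentError("max_lag must be shorter than the train duration")
    if max_lag < 0:
        raise InvalidArgumentError("max_lag must be nonnegative")
    x = train.values.astype(np.float64)
    x -= x.mean()
    c0 = float(np.dot(x, x))
    if c0 == 0.0:
        raise DegenerateDataError("autocorrelation undefined for a zero-variance train")
    n_lags = int(np.floor(max_lag / train.dt + 1e-9)) + 1
    lags = train.dt * np.arange(n_lags)
    values = np.empty(n_lags)
    values[0] = 1.0
    for k in range(1, n_lags):
        # biased estimator: normalize by the full-length lag-0 sum
        values[k] = float(np.dot(x[:-k], x[k:])) / c0
    return np.column_stack([lags, values])
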