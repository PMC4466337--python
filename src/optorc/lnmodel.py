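"""Linear-nonlinear model: convolution prediction, static-nonlinearity
estimation, and transition-probability prediction for arbitrary stimuli.

The linear stage convolves a causal kernel with the +/-1 stimulus to give
a drive in rate units (events/s).  The static nonlinearity is a memoryless
map from drive to a nonnegative transition rate, fitted by least squares
on equal-count drive bins.  Predictions convert rates to per-bin
transition probabilities via ``p = 1 - exp(-rate * dt)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    EmptyResultError,
    FitFailureError,
    InvalidArgumentError,
)
from .events import RUN_TO_TURN, TURN_TO_RUN
from .revcorr import LinearFilter
from .stimulus import StimulusTrain
from .tracks import StateTrack

__all__ = [
    "StaticNonlinearity",
    "LNModel",
    "RateTrace",
    "PredictionTrace",
    "EmpiricalPSTH",
    "linear_predict",
    "estimate_nonlinearity",
    "predict_response",
    "empirical_psth",
]

_AT_RISK_CODE = {RUN_TO_TURN: 0, TURN_TO_RUN: 1}


def _sigmoid(x, floor, amplitude, slope, midpoint):
    return floor + amplitude / (1.0 + np.exp(-slope * (x - midpoint)))


@dataclass(frozen=True)
class StaticNonlinearity:
    """Memoryless drive-to-rate map, either sigmoidal or linear.

    Sigmoid: ``floor + amplitude / (1 + exp(-slope * (x - midpoint)))``.
    Linear: ``intercept + gain * x``.  Evaluated output is clipped at 0
    because rates are nonnegative.
    """

    form: str
    params: dict = field(default_factory=dict)
    goodness: float | None = None

    def __post_init__(self) -> None:
        if self.form == "sigmoid":
            required = {"floor", "amplitude", "slope", "midpoint"}
        elif self.form == "linear":
            required = {"intercept", "gain"}
        elif self.form == "constant":
            required = {"rate"}
        else:
            raise InvalidArgumentError(f"unknown nonlinearity form {self.form!r}")
        missing = required - set(self.params)
        if missing:
            raise InvalidArgumentError(f"missing {self.form} parameters: {sorted(missing)}")
        if self.form == "sigmoid" and self.params["amplitude"] < 0:
            raise InvalidArgumentError("sigmoid amplitude must be nonnegative")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.form == "sigmoid":
            out = _sigmoid(x, p["floor"], p["amplitude"], p["slope"], p["midpoint"])
        elif self.form == "linear":
            out = p["intercept"] + p["gain"] * x
        else:
            out = np.full_like(x, p["rate"])
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class LNModel:
    """Pair of linear filters plus pair of static nonlinearities — the
    full two-state navigation model."""

    filter_rt: LinearFilter | None = None
    filter_tr: LinearFilter | None = None
    nonlin_rt: StaticNonlinearity | None = None
    nonlin_tr: StaticNonlinearity | None = None
    provenance: dict = field(default_factory=dict)

    def components(self, kind: str) -> tuple[LinearFilter, StaticNonlinearity]:
        if kind == RUN_TO_TURN:
            filt, nonlin = self.filter_rt, self.nonlin_rt
        elif kind == TURN_TO_RUN:
            filt, nonlin = self.filter_tr, self.nonlin_tr
        else:
            raise InvalidArgumentError(f"unknown transition kind {kind!r}")
        if filt is None or nonlin is None:
            raise InvalidArgumentError(f"model is incomplete for kind {kind!r}")
        return filt, nonlin

    @property
    def kinds(self) -> list[str]:
        out = []
        if self.filter_rt is not None and self.nonlin_rt is not None:
            out.append(RUN_TO_TURN)
        if self.filter_tr is not None and self.nonlin_tr is not None:
            out.append(TURN_TO_RUN)
        return out


@dataclass(frozen=True)
class RateTrace:
    """Linearly predicted rate (events/s) on the stimulus clock; the
    first ``n_burnin`` bins lack full stimulus history."""

    t0: float
    dt: float
    rate: np.ndarray = field(repr=False)
    n_burnin: int = 0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.rate.size)

    @property
    def burnin_mask(self) -> np.ndarray:
        mask = np.zeros(self.rate.size, dtype=bool)
        mask[: self.n_burnin] = True
        return mask


@dataclass(frozen=True)
class PredictionTrace:
    """Predicted per-bin transition probability for one transition kind."""

    times: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    kind: str = RUN_TO_TURN
    n_burnin: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise InvalidArgumentError("predicted probabilities must lie in [0, 1]")
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))


@dataclass(frozen=True)
class EmpiricalPSTH:
    """Observed per-bin transition probability aligned to repeated
    stimulus events; ``n`` counts at-risk animals and ``k`` transitions."""

    times: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)
    k: np.ndarray = field(repr=False)
    kind: str = RUN_TO_TURN

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        n = np.asarray(self.n, dtype=np.int64)
        k = np.asarray(self.k, dtype=np.int64)
        if np.any((p < 0) | (p > 1)) or np.any(n < 0):
            raise InvalidArgumentError("PSTH requires 0 <= p <= 1 and n >= 0")
        if np.any(np.abs(p * n - k) > 1e-9):
            raise InvalidArgumentError("p * n must be integral (the transition count)")
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)


def linear_predict(filt: LinearFilter, stim: StimulusTrain) -> RateTrace:
    """Causal discrete convolution ``r(t) = sum_k h(tau_k) s(t - tau_k) dt``.

    The first ``n_taps - 1`` bins are flagged as burn-in: there the
    convolution window reaches before the start of the stimulus.
    """
    if not math.isclose(filt.dt, stim.dt, rel_tol=1e-9):
        raise InvalidArgumentError(
            f"filter dt ({filt.dt}) does not match stimulus dt ({stim.dt})"
        )
    s = stim.values.astype(np.float64)
    rate = np.convolve(s, filt.h)[: stim.n_samples] * stim.dt
    return RateTrace(t0=stim.t0, dt=stim.dt, rate=rate, n_burnin=filt.n_taps - 1)


def _pool_at_risk(
    drive: RateTrace | list[RateTrace],
    tracks: list[StateTrack],
    kind: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pool (drive value, transition indicator) over all at-risk bins of
    all tracks, excluding burn-in bins."""
    at_risk = _AT_RISK_CODE[kind]
    drives = drive if isinstance(drive, list) else [drive] * len(tracks)
    if len(drives) != len(tracks):
        raise InvalidArgumentError("need one drive trace per track (or a single shared one)")
    xs, ys = [], []
    dt = None
    for dr, track in zip(drives, tracks):
        if not math.isclose(dr.dt, track.dt, rel_tol=1e-9):
            raise InvalidArgumentError("drive and track sample intervals differ")
        dt = track.dt
        # map track bins onto the drive clock; the drive at bin k governs
        # whether a new state begins at bin k
        offset = int(round((track.t0 - dr.t0) / dr.dt))
        codes = track.states
        n = min(track.n_samples, dr.rate.size - offset)
        if n <= 1:
            continue
        k_idx = np.arange(1, n)
        mask = codes[k_idx - 1] == at_risk
        mask &= (k_idx + offset) >= dr.n_burnin
        xs.append(dr.rate[k_idx[mask] + offset])
        ys.append((codes[k_idx[mask]] != codes[k_idx[mask] - 1]).astype(np.float64))
    if not xs:
        raise EmptyResultError("no at-risk bins found")
    return np.concatenate(xs), np.concatenate(ys), float(dt)


def _fit_linear(x: np.ndarray, y: np.ndarray) -> tuple[dict, float]:
    gain, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + gain * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return {"intercept": float(intercept), "gain": float(gain)}, r2


def _fit_sigmoid(x: np.ndarray, y: np.ndarray) -> tuple[dict, float]:
    lo, hi = float(y.min()), float(y.max())
    span = max(hi - lo, 1e-12)
    x_scale = max(float(x.std()), 1e-12)
    sign = 1.0 if np.corrcoef(x, y)[0, 1] >= 0 else -1.0
    p0 = (lo, span, sign * 2.0 / x_scale, float(np.median(x)))
    bounds = ([-np.inf, 0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(_sigmoid, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"sigmoid fit did not converge: {exc}") from exc
    resid = y - _sigmoid(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    params = dict(zip(("floor", "amplitude", "slope", "midpoint"), map(float, popt)))
    return params, r2


def estimate_nonlinearity(
    linear_drive: RateTrace | list[RateTrace],
    tracks: list[StateTrack],
    kind: str,
    n_bins: int = 20,
    form: str = "sigmoid",
    exact_hazard: bool = True,
) -> StaticNonlinearity:
    """Fit a static nonlinearity mapping linear drive to empirical rate.

    All time bins where an animal occupies the at-risk state are pooled
    and split into ``n_bins`` equal-count bins by drive value.  The
    empirical rate in each bin is the per-bin transition probability
    converted to a rate: exactly, ``-ln(1 - p) / dt`` (default), or by
    the small-rate approximation ``p / dt`` when ``exact_hazard`` is
    False.  The chosen functional form is then fitted by least squares
    on (bin mean drive, rate) pairs; ``form='auto'`` picks sigmoid or
    linear by adjusted R-squared.

    Raises
    ------
    FitFailureError
        If the drive carries no variation or there are fewer nonempty
        bins than free parameters.
    """
    if n_bins < 3:
        raise InvalidArgumentError("n_bins must be at least 3")
    if form not in ("sigmoid", "linear", "auto"):
        raise InvalidArgumentError(f"unknown form {form!r}")
    x, y, dt = _pool_at_risk(linear_drive, tracks, kind)
    if float(x.std()) < 1e-12:
        raise FitFailureError("linear drive has no variation; nonlinearity is unidentifiable")
    order = np.argsort(x, kind="stable")
    chunks = np.array_split(order, n_bins)
    bin_x, bin_rate = [], []
    for chunk in chunks:
        if chunk.size == 0:
            continue
        p_hat = float(y[chunk].mean())
        p_hat = min(p_hat, 1.0 - 0.5 / chunk.size)
        rate = -math.log1p(-p_hat) / dt if exact_hazard else p_hat / dt
        bin_x.append(float(x[chunk].mean()))
        bin_rate.append(rate)
    bin_x = np.asarray(bin_x)
    bin_rate = np.asarray(bin_rate)
    n_params = {"linear": 2, "sigmoid": 4, "auto": 4}[form]
    if bin_x.size < n_params:
        raise FitFailureError(
            f"only {bin_x.size} nonempty bins for a {n_params}-parameter fit"
        )
    if form == "linear":
        params, r2 = _fit_linear(bin_x, bin_rate)
        return StaticNonlinearity("linear", params, goodness=r2)
    if form == "sigmoid":
        params, r2 = _fit_sigmoid(bin_x, bin_rate)
        return StaticNonlinearity("sigmoid", params, goodness=r2)
    # automatic choice by adjusted R^2
    lin_params, lin_r2 = _fit_linear(bin_x, bin_rate)
    try:
        sig_params, sig_r2 = _fit_sigmoid(bin_x, bin_rate)
    except FitFailureError:
        return StaticNonlinearity("linear", lin_params, goodness=lin_r2)
    m = bin_x.size

    def adj(r2, k):
        return 1.0 - (1.0 - r2) * (m - 1) / max(m - k - 1, 1)

    if adj(sig_r2, 4) >= adj(lin_r2, 2):
        return StaticNonlinearity("sigmoid", sig_params, goodness=sig_r2)
    return StaticNonlinearity("linear", lin_params, goodness=lin_r2)


def predict_response(
    model: LNModel,
    stim: StimulusTrain,
    kinds: list[str] | None = None,
) -> dict[str, PredictionTrace]:
    """LN prediction of per-bin transition probability for each kind:
    ``p(t) = 1 - exp(-N((h * s)(t)) dt)``, burn-in bins flagged."""
    kinds = kinds if kinds is not None else model.kinds
    if not kinds:
        raise InvalidArgumentError("model has no complete transition kind")
    out = {}
    for kind in kinds:
        filt, nonlin = model.components(kind)
        drive = linear_predict(filt, stim)
        rate = nonlin(drive.rate)
        p = 1.0 - np.exp(-rate * stim.dt)
        out[kind] = PredictionTrace(
            times=drive.times, p=p, kind=kind, n_burnin=drive.n_burnin
        )
    return out


def empirical_psth(
    tracks: list[StateTrack],
    align_times: list[float],
    window: tuple[float, float],
    kind: str,
) -> EmpiricalPSTH:
    """Observed transition probability per relative-time bin.

    For each alignment time and track, a bin at relative time ``tau``
    contributes if the animal occupied the at-risk state in the preceding
    sample; it counts as a transition if the new state begins in the bin.
    ``p`` is transitions / at-risk count per bin; ``n`` is retained for
    z-tests.
    """
    if kind not in _AT_RISK_CODE:
        raise InvalidArgumentError(f"unknown transition kind {kind!r}")
    if not tracks or not align_times:
        raise InvalidArgumentError("need at least one track and one alignment time")
    lo, hi = window
    if hi <= lo:
        raise InvalidArgumentError("window must satisfy lo < hi")
    at_risk = _AT_RISK_CODE[kind]
    dt = tracks[0].dt
    j_lo = int(round(lo / dt))
    j_hi = int(round(hi / dt))
    offsets = np.arange(j_lo, j_hi + 1)
    n = np.zeros(offsets.size, dtype=np.int64)
    k = np.zeros(offsets.size, dtype=np.int64)
    for track in tracks:
        if not math.isclose(track.dt, dt, rel_tol=1e-9):
            raise InvalidArgumentError("tracks must share one sample interval")
        codes = track.states
        for t_a in align_times:
            a = int(round((t_a - track.t0) / dt))
            idx = a + offsets
            ok = (idx >= 1) & (idx <= track.n_samples - 1)
            risk = ok.copy()
            risk[ok] = codes[idx[ok] - 1] == at_risk
            n += risk
            trans = risk.copy()
            trans[risk] = codes[idx[risk]] != codes[idx[risk] - 1]
            k += trans
    if n.sum() == 0:
        raise EmptyResultError("no at-risk samples in any bin")
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    return EmpiricalPSTH(times=offsets * dt, p=p, n=n, k=k, kind=kind)
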