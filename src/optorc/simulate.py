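"""Ground-truth LN-driven two-state stochastic simulator.

Populations of animals alternate between RUN and TURN; the hazard of
leaving the current state is the ground-truth nonlinearity applied to the
convolution of the matching filter with the stimulus.  A transition
occurs in a bin with probability ``1 - exp(-rate * dt)`` — exact for the
underlying inhomogeneous point process, and valid for any nonnegative
rate.

Reproducibility: animal ``i`` uses the i-th child of
``numpy.random.SeedSequence(seed)`` (its spawn key), so a population is
reproducible animal-by-animal regardless of batch size or population
size, and every animal's stream is independent of a stimulus generated
with the same integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, SimulationError
from .lnmodel import LNModel, StaticNonlinearity, linear_predict
from .revcorr import LinearFilter
from .stimulus import StimulusTrain
from .tracks import RUN, TURN, StateTrack

__all__ = [
    "GroundTruthLN",
    "SpeedModel",
    "StateTrack",
    "RUN",
    "TURN",
    "GROUND_TRUTH_KINDS",
    "default_ground_truth",
    "simulate_population",
]

#: Named parametric ground-truth models (valence x filter shape).
GROUND_TRUTH_KINDS = (
    "attractive-monophasic",
    "attractive-biphasic",
    "repulsive-monophasic",
    "repulsive-biphasic",
)


@dataclass(frozen=True)
class GroundTruthLN:
    """Known filters and nonlinearities used to generate synthetic data."""

    filter_rt: LinearFilter
    filter_tr: LinearFilter
    nonlin_rt: StaticNonlinearity
    nonlin_tr: StaticNonlinearity

    def as_ln_model(self) -> LNModel:
        return LNModel(
            filter_rt=self.filter_rt,
            filter_tr=self.filter_tr,
            nonlin_rt=self.nonlin_rt,
            nonlin_tr=self.nonlin_tr,
            provenance={"source": "ground truth"},
        )


@dataclass(frozen=True)
class SpeedModel:
    """Per-state Gaussian speed levels with a linear deceleration ramp
    starting ``decel_lead`` seconds before each run-to-turn transition."""

    run_mean: float = 2.0
    run_sd: float = 0.15
    turn_mean: float = 0.5
    turn_sd: float = 0.1
    decel_lead: float = 1.0

    def __post_init__(self) -> None:
        if not self.run_mean > self.turn_mean >= 0:
            raise InvalidArgumentError("require run_mean > turn_mean >= 0")
        if self.run_sd < 0 or self.turn_sd < 0:
            raise InvalidArgumentError("speed standard deviations must be nonnegative")
        if self.decel_lead < 0:
            raise InvalidArgumentError("decel_lead must be nonnegative")


def _alpha_lobe(taus: np.ndarray, peak: float, order: int = 1) -> np.ndarray:
    """Unit-peak alpha-function lobe ``(tau/peak)^n exp(n (1 - tau/peak))``
    peaking at ``peak`` seconds; higher ``order`` rises more gradually."""
    x = taus / peak
    return x**order * np.exp(order * (1.0 - x))


def default_ground_truth(kind: str, dt: float = 0.25) -> GroundTruthLN:
    """A documented parametric ground-truth model of the named class.

    Filter support is 3 s (shorter than the 4 s history bound).  Run-to-
    turn filters: monophasic kinds carry a single alpha lobe peaking
    1.0 s before the event; biphasic kinds carry a faster lobe peaking at
    0.5 s opposed by an earlier lobe peaking at 2 s whose weight makes
    the kernel integrate to zero, so step responses are fast and purely
    transient (full adaptation).  Repulsive models have a positive
    run-to-turn lobe near the event and a negative turn-to-run filter;
    attractive models are sign-flipped.  Nonlinearities are sigmoids with
    positive baselines.
    """
    if kind not in GROUND_TRUTH_KINDS:
        raise InvalidArgumentError(
            f"unknown ground-truth kind {kind!r}; choose from {GROUND_TRUTH_KINDS}"
        )
    valence, shape = kind.split("-")
    sign = 1.0 if valence == "repulsive" else -1.0
    taus = dt * np.arange(int(round(3.0 / dt)))
    if shape == "biphasic":
        lobe = _alpha_lobe(taus, 0.5)
        opposing = _alpha_lobe(taus, 2.0)
        h_rt = sign * (lobe - (lobe.sum() / opposing.sum()) * opposing)
    else:
        h_rt = sign * _alpha_lobe(taus, 1.0, order=2)
    h_tr = -sign * 0.6 * _alpha_lobe(taus, 0.5)
    return GroundTruthLN(
        filter_rt=LinearFilter(taus=taus, h=h_rt, dt=dt, kind="RUN_TO_TURN"),
        filter_tr=LinearFilter(taus=taus, h=h_tr, dt=dt, kind="TURN_TO_RUN"),
        nonlin_rt=StaticNonlinearity(
            "sigmoid", {"floor": 0.02, "amplitude": 0.25, "slope": 3.0, "midpoint": 0.0}
        ),
        nonlin_tr=StaticNonlinearity(
            "sigmoid", {"floor": 0.3, "amplitude": 1.0, "slope": 3.0, "midpoint": 0.0}
        ),
    )


def _transition_probabilities(
    model: GroundTruthLN, stim: StimulusTrain
) -> tuple[np.ndarray, np.ndarray]:
    p = []
    for filt, nonlin in (
        (model.filter_rt, model.nonlin_rt),
        (model.filter_tr, model.nonlin_tr),
    ):
        drive = linear_predict(filt, stim)
        rate = nonlin(drive.rate)
        bad = np.flatnonzero(~np.isfinite(rate))
        if bad.size:
            t_bad = stim.t0 + bad[0] * stim.dt
            raise SimulationError(
                f"non-finite hazard at time bin {bad[0]} (t = {t_bad:.3f} s)"
            )
        p.append(1.0 - np.exp(-rate * stim.dt))
    return p[0], p[1]


def _simulate_states_batch(
    p_rt: np.ndarray, p_tr: np.ndarray, uniforms: np.ndarray
) -> np.ndarray:
    """Vectorized two-state walk for a batch of animals.

    ``uniforms`` has shape (batch, n_bins); ``uniforms[:, k]`` decides
    whether a new state begins at bin k, with the hazard evaluated from
    the drive at bin k (so an event's first sample is aligned with the
    stimulus history that produced it).  All animals start in RUN.
    """
    batch, n = uniforms.shape
    states = np.zeros((batch, n), dtype=np.int8)
    cur = np.zeros(batch, dtype=np.int8)
    for k in range(1, n):
        p_leave = np.where(cur == 0, p_rt[k], p_tr[k])
        flip = uniforms[:, k] < p_leave
        cur = np.where(flip, 1 - cur, cur).astype(np.int8)
        states[:, k] = cur
    return states


def _speed_trace(
    states: np.ndarray, dt: float, speed_model: SpeedModel, rng: np.random.Generator
) -> np.ndarray:
    sm = speed_model
    mean = np.where(states == 0, sm.run_mean, sm.turn_mean)
    sd = np.where(states == 0, sm.run_sd, sm.turn_sd)
    lead = int(round(sm.decel_lead / dt))
    if lead > 0:
        onsets = np.flatnonzero(np.diff(states) == 1) + 1  # first TURN samples
        for i in onsets:
            for j in range(max(i - lead, 0), i):
                if states[j] != 0:
                    continue  # ramp only over RUN samples
                frac = (j - (i - lead)) / lead
                mean[j] = sm.run_mean + (sm.turn_mean - sm.run_mean) * frac
    return mean + sd * rng.standard_normal(states.size)


def simulate_population(
    model: GroundTruthLN,
    stim: StimulusTrain,
    n_animals: int,
    seed: int,
    speed_model: SpeedModel | None = None,
    burn_in: float = 10.0,
    batch_size: int = 2000,
) -> list[StateTrack]:
    """Simulate a population of two-state tracks driven by the model.

    The first ``burn_in`` seconds are discarded from the returned tracks
    (their ``t0`` reflects the discarded span) to erase the all-RUN
    initial condition; the retained samples stay aligned to the stimulus
    clock.
    """
    if n_animals < 1:
        raise InvalidArgumentError("n_animals must be at least 1")
    if model.filter_rt.support >= stim.duration or model.filter_tr.support >= stim.duration:
        raise InvalidArgumentError("filters must be shorter than the stimulus")
    if burn_in < 0 or burn_in >= stim.duration:
        raise InvalidArgumentError("burn_in must lie in [0, duration)")
    p_rt, p_tr = _transition_probabilities(model, stim)
    n = stim.n_samples
    b = int(round(burn_in / stim.dt))
    t0 = stim.t0 + b * stim.dt
    tracks: list[StateTrack] = []
    for start in range(0, n_animals, batch_size):
        stop = min(start + batch_size, n_animals)
        children = np.random.SeedSequence(seed).spawn(stop)[start:stop]
        rngs = [np.random.default_rng(c) for c in children]
        uniforms = np.stack([rng.random(n) for rng in rngs])
        states = _simulate_states_batch(p_rt, p_tr, uniforms)
        for row, (i, rng) in zip(states, zip(range(start, stop), rngs)):
            speed = None
            if speed_model is not None:
                speed = _speed_trace(row, stim.dt, speed_model, rng)[b:]
            tracks.append(
                StateTrack(
                    animal_id=f"animal-{i:05d}",
                    t0=t0,
                    dt=stim.dt,
                    states=row[b:],
                    speed=speed,
                )
            )
    return tracks
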