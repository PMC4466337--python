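import numpy as np
import pytest

from conftest import constant_hazard_model
from optorc import (
    RUN_TO_TURN,
    TURN_TO_RUN,
    TransitionEvent,
    default_ground_truth,
    extract_transitions,
    filter_from_ta,
    generate_bernoulli,
    simulate_population,
    triggered_average,
)
from optorc.errors import EmptyResultError, InvalidArgumentError
from optorc.stimulus import StimulusTrain


def brute_force_ta(events, stim, kind, window):
    """Naive double-loop oracle for the event-triggered average."""
    n_lags = int(round(window / stim.dt)) + 1
    rows = []
    for ev in events:
        if ev.kind != kind:
            continue
        k = stim.index_at(ev.time)
        if k - (n_lags - 1) < 0 or k >= stim.n_samples:
            continue
        row = [stim.values[k + lag] for lag in range(-(n_lags - 1), 1)]
        rows.append(row)
    rows = np.array(rows, dtype=float)
    return rows.mean(axis=0), rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0])


class TestTriggeredAverage:
    def test_matches_brute_force_oracle(self):
        # fixed 200-sample stimulus, 10 hand-placed events
        stim = generate_bernoulli(50.0, 0.25, 0.5, seed=42)
        assert stim.n_samples == 200
        times = [5.0, 7.25, 10.0, 13.5, 20.0, 25.75, 30.0, 35.25, 40.0, 45.5]
        events = [TransitionEvent("a", t, RUN_TO_TURN) for t in times]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
        mean_o, sem_o = brute_force_ta(events, stim, RUN_TO_TURN, 2.0)
        assert ta.n_events == 10
        np.testing.assert_allclose(ta.mean, mean_o, rtol=0, atol=1e-15)
        np.testing.assert_allclose(ta.sem, sem_o, rtol=0, atol=1e-15)

    def test_constant_stimulus(self):
        stim = StimulusTrain(0.0, 0.25, np.ones(100, dtype=int))
        events = [TransitionEvent("a", t, RUN_TO_TURN) for t in (10.0, 15.0, 20.0)]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
        assert (ta.mean == 1.0).all()
        assert (ta.sem == 0.0).all()

    def test_single_event_identity(self):
        stim = generate_bernoulli(10.0, 0.25, 0.5, seed=8)
        ta = triggered_average([TransitionEvent("a", 2.0, RUN_TO_TURN)], stim,
                               RUN_TO_TURN, window=1.0)
        assert ta.n_events == 1
        np.testing.assert_array_equal(ta.mean, stim.values[4:9].astype(float))
        assert (ta.sem == 0.0).all()

    def test_independent_events_flat(self):
        # 10^4 events placed independently of the stimulus -> |mean| < 3/sqrt(n)
        stim = generate_bernoulli(5000.0, 0.25, 0.5, seed=2024)
        rng = np.random.default_rng(2024)
        times = np.sort(rng.uniform(10.0, 4990.0, size=10**4))
        events = [TransitionEvent("a", t, RUN_TO_TURN) for t in times]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
        assert np.all(np.abs(ta.mean) < 3.0 / np.sqrt(ta.n_events))

    def test_incomplete_history_excluded(self):
        stim = generate_bernoulli(20.0, 0.25, 0.5, seed=10)
        events = [
            TransitionEvent("a", 0.5, RUN_TO_TURN),   # history runs off the start
            TransitionEvent("a", 10.0, RUN_TO_TURN),
        ]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
        assert ta.n_events == 1
        assert ta.n_excluded == 1

    def test_no_usable_events(self):
        stim = generate_bernoulli(20.0, 0.25, 0.5, seed=10)
        with pytest.raises(EmptyResultError):
            triggered_average([TransitionEvent("a", 0.25, RUN_TO_TURN)], stim,
                              RUN_TO_TURN, window=2.0)

    def test_window_longer_than_stimulus_rejected(self):
        stim = generate_bernoulli(2.0, 0.25, 0.5, seed=1)
        with pytest.raises(InvalidArgumentError):
            triggered_average([], stim, RUN_TO_TURN, window=5.0)

    def test_sem_shrinks_as_sqrt_n(self):
        stim = generate_bernoulli(3 * 10**4, 0.25, 0.5, seed=3)
        rng = np.random.default_rng(3)
        sems = []
        for n in (10**2, 10**3, 10**4):
            times = rng.uniform(10.0, stim.duration - 1, size=n)
            events = [TransitionEvent("a", t, RUN_TO_TURN) for t in times]
            ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
            sems.append(ta.sem.mean())
        assert sems[0] / sems[1] == pytest.approx(np.sqrt(10), rel=0.15)
        assert sems[1] / sems[2] == pytest.approx(np.sqrt(10), rel=0.15)


class TestFilterFromTa:
    def test_scaling_constant_ta(self):
        stim = StimulusTrain(0.0, 0.25, np.ones(100, dtype=int))
        events = [TransitionEvent("a", t, RUN_TO_TURN) for t in (10.0, 15.0)]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
        filt = filter_from_ta(ta, mean_events_per_trial=10, trial_duration=1200.0)
        assert np.allclose(filt.h, 10 / 1200.0)
        assert filt.taus[0] == 0.0
        assert filt.taus[-1] == pytest.approx(2.0)

    def test_zero_ta_gives_zero_filter(self):
        ta_mean = np.zeros(9)
        stim = generate_bernoulli(100.0, 0.25, 0.5, seed=2)
        events = [TransitionEvent("a", 50.0, RUN_TO_TURN)]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
        object.__setattr__(ta, "mean", ta_mean)
        filt = filter_from_ta(ta, 10, 1200.0)
        assert (filt.h == 0.0).all()

    def test_nonpositive_trial_duration_rejected(self):
        stim = generate_bernoulli(100.0, 0.25, 0.5, seed=2)
        ta = triggered_average([TransitionEvent("a", 50.0, RUN_TO_TURN)], stim,
                               RUN_TO_TURN, 2.0)
        with pytest.raises(InvalidArgumentError):
            filter_from_ta(ta, 10, 0.0)

    def test_time_reversal_bookkeeping(self):
        # lag -0.5 s in the TA must land at tau = +0.5 s in the filter
        stim = generate_bernoulli(100.0, 0.25, 0.5, seed=2)
        ta = triggered_average([TransitionEvent("a", 50.0, RUN_TO_TURN)], stim,
                               RUN_TO_TURN, 2.0)
        filt = filter_from_ta(ta, 1200.0, 1200.0)  # scale = 1
        i_lag = np.flatnonzero(np.isclose(ta.lags, -0.5))[0]
        i_tau = np.flatnonzero(np.isclose(filt.taus, 0.5))[0]
        assert filt.h[i_tau] == pytest.approx(ta.mean[i_lag])


class TestRecovery:
    def test_biphasic_filter_recovery(self):
        # parameter-recovery oracle via the simulator
        stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=21)
        gt = default_ground_truth("repulsive-biphasic")
        tracks = simulate_population(gt, stim, 120, seed=21)
        events = [e for tr in tracks for e in extract_transitions(tr)]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=4.0)
        filt = filter_from_ta(ta, ta.n_events / len(tracks), 1200.0)
        truth = np.zeros_like(filt.h)
        truth[: gt.filter_rt.h.size] = gt.filter_rt.h
        r = np.corrcoef(filt.h, truth)[0, 1]
        assert r >= 0.9

    def test_impulse_dependency_peak_location(self):
        # ground-truth filter concentrated at tau* = 1.0 s
        from optorc import LinearFilter, StaticNonlinearity
        from optorc.simulate import GroundTruthLN

        taus = 0.25 * np.arange(8)
        h = np.zeros(8)
        h[4] = 2.0  # impulse at tau = 1.0 s
        gt = GroundTruthLN(
            filter_rt=LinearFilter(taus=taus, h=h, dt=0.25),
            filter_tr=LinearFilter(taus=taus, h=np.zeros(8), dt=0.25,
                                   kind=TURN_TO_RUN),
            nonlin_rt=StaticNonlinearity("linear", {"intercept": 0.6, "gain": 0.6}),
            nonlin_tr=StaticNonlinearity("constant", {"rate": 0.8}),
        )
        stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=13)
        tracks = simulate_population(gt, stim, 100, seed=13)
        events = [e for tr in tracks for e in extract_transitions(tr)]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
        filt = filter_from_ta(ta, ta.n_events / len(tracks), 1200.0)
        peak = filt.taus[np.argmax(np.abs(filt.h))]
        assert abs(peak - 1.0) <= 0.25

    def test_null_calibration_2sem_band(self):
        # stimulus-independent events: ~5% of lags outside mean +/- 2 sem.
        # Low event density keeps events on distinct stimulus samples, so
        # the independent-event SEM is the right scale.
        outside = 0
        total = 0
        for seed in range(100):
            stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=seed)
            model = constant_hazard_model(0.25, 0.25)
            tracks = simulate_population(model, stim, 3, seed=seed)
            events = [e for tr in tracks for e in extract_transitions(tr)]
            ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
            outside += int(np.sum(np.abs(ta.mean) > 2 * ta.sem))
            total += ta.mean.size
        frac = outside / total
        assert 0.02 < frac < 0.08
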