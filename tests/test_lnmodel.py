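import numpy as np
import pytest

from conftest import constant_hazard_model
from optorc import (
    RUN_TO_TURN,
    TURN_TO_RUN,
    LinearFilter,
    LNModel,
    StateTrack,
    StaticNonlinearity,
    default_ground_truth,
    empirical_psth,
    estimate_nonlinearity,
    generate_bernoulli,
    linear_predict,
    make_step,
    predict_response,
    simulate_population,
)
from optorc.errors import (
    EmptyResultError,
    FitFailureError,
    InvalidArgumentError,
)
from optorc.simulate import GroundTruthLN


class TestStaticNonlinearity:
    def test_sigmoid_bounds_and_monotonicity(self):
        nl = StaticNonlinearity(
            "sigmoid", {"floor": 0.1, "amplitude": 0.5, "slope": 2.0, "midpoint": 0.0}
        )
        x = np.linspace(-50, 50, 1001)
        y = nl(x)
        assert (np.diff(y) >= 0).all()
        assert y.min() >= 0.1 - 1e-12
        assert y.max() <= 0.6 + 1e-12

    def test_linear_clipped_at_zero(self):
        nl = StaticNonlinearity("linear", {"intercept": 0.0, "gain": 1.0})
        assert nl(-5.0) == 0.0
        assert nl(2.0) == 2.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidArgumentError):
            StaticNonlinearity(
                "sigmoid", {"floor": 0, "amplitude": -1, "slope": 1, "midpoint": 0}
            )

    def test_missing_params_rejected(self):
        with pytest.raises(InvalidArgumentError):
            StaticNonlinearity("linear", {"intercept": 0.1})


class TestLinearPredict:
    def test_identity_kernel(self):
        stim = generate_bernoulli(10.0, 0.25, 0.5, seed=0)
        filt = LinearFilter(taus=np.array([0.0]), h=np.array([4.0]), dt=0.25)  # 1/dt
        trace = linear_predict(filt, stim)
        np.testing.assert_allclose(trace.rate, stim.values.astype(float))

    def test_zero_kernel(self):
        stim = generate_bernoulli(10.0, 0.25, 0.5, seed=0)
        filt = LinearFilter(taus=np.array([0.0, 0.25]), h=np.zeros(2), dt=0.25)
        assert (linear_predict(filt, stim).rate == 0.0).all()

    def test_boxcar_step_ramp(self):
        # boxcar over [0, 1] s convolved with a step ramps linearly over 1 s
        stim = make_step(10.0, 0.25, [5.0], initial=-1)
        filt = LinearFilter(taus=0.25 * np.arange(4), h=np.ones(4), dt=0.25)
        trace = linear_predict(filt, stim)
        area = 4 * 0.25
        np.testing.assert_allclose(trace.rate[16:20], -area)  # steady -1
        ramp = trace.rate[20:24]
        np.testing.assert_allclose(np.diff(ramp), 2 * 0.25, atol=1e-12)
        np.testing.assert_allclose(trace.rate[24:], area)  # steady +1

    def test_burnin_flagging(self):
        stim = generate_bernoulli(10.0, 0.25, 0.5, seed=0)
        filt = LinearFilter(taus=0.25 * np.arange(8), h=np.ones(8), dt=0.25)
        trace = linear_predict(filt, stim)
        assert trace.n_burnin == 7
        assert trace.burnin_mask.sum() == 7

    def test_dt_mismatch_rejected(self):
        stim = generate_bernoulli(10.0, 0.25, 0.5, seed=0)
        filt = LinearFilter(taus=np.array([0.0]), h=np.array([1.0]), dt=0.5)
        with pytest.raises(InvalidArgumentError):
            linear_predict(filt, stim)


class TestEstimateNonlinearity:
    def test_linear_recovery(self):
        stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=30)
        gt = default_ground_truth("repulsive-monophasic")
        lin = StaticNonlinearity("linear", {"intercept": 0.4, "gain": 0.25})
        model = GroundTruthLN(gt.filter_rt, gt.filter_tr, lin, gt.nonlin_tr)
        tracks = simulate_population(model, stim, 100, seed=30)
        drive = linear_predict(gt.filter_rt, stim)
        fit = estimate_nonlinearity(drive, tracks, RUN_TO_TURN, n_bins=20, form="linear")
        assert fit.params["intercept"] == pytest.approx(0.4, rel=0.10)
        assert fit.params["gain"] == pytest.approx(0.25, rel=0.10)

    def test_sigmoid_recovery(self):
        stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=31)
        gt = default_ground_truth("repulsive-monophasic")
        tracks = simulate_population(gt, stim, 100, seed=31)
        drive = linear_predict(gt.filter_rt, stim)
        fit = estimate_nonlinearity(drive, tracks, RUN_TO_TURN, n_bins=20, form="sigmoid")
        truth = gt.nonlin_rt.params
        assert fit.params["slope"] == pytest.approx(truth["slope"], rel=0.2)
        # truth midpoint is 0: compare on the drive scale instead of relative
        drive_sd = drive.rate[drive.n_burnin:].std()
        assert abs(fit.params["midpoint"] - truth["midpoint"]) < 0.2 * drive_sd

    def test_zero_drive_fit_failure(self):
        stim = generate_bernoulli(300.0, 0.25, 0.5, seed=32)
        model = constant_hazard_model(0.2, 0.5)
        tracks = simulate_population(model, stim, 5, seed=32)
        drive = linear_predict(model.filter_rt, stim)
        with pytest.raises(FitFailureError):
            estimate_nonlinearity(drive, tracks, RUN_TO_TURN, n_bins=10)

    def test_auto_prefers_linear_for_linear_truth(self):
        stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=33)
        gt = default_ground_truth("repulsive-monophasic")
        lin = StaticNonlinearity("linear", {"intercept": 0.4, "gain": 0.25})
        model = GroundTruthLN(gt.filter_rt, gt.filter_tr, lin, gt.nonlin_tr)
        tracks = simulate_population(model, stim, 60, seed=33)
        drive = linear_predict(gt.filter_rt, stim)
        fit = estimate_nonlinearity(drive, tracks, RUN_TO_TURN, n_bins=20, form="auto")
        assert fit.goodness > 0.8

    def test_too_few_bins_rejected(self):
        stim = generate_bernoulli(300.0, 0.25, 0.5, seed=34)
        gt = default_ground_truth("repulsive-monophasic")
        tracks = simulate_population(gt, stim, 2, seed=34)
        drive = linear_predict(gt.filter_rt, stim)
        with pytest.raises(InvalidArgumentError):
            estimate_nonlinearity(drive, tracks, RUN_TO_TURN, n_bins=2)


class TestPredictResponse:
    def test_constant_nonlinearity(self):
        stim = generate_bernoulli(100.0, 0.25, 0.5, seed=1)
        model = LNModel(
            filter_rt=LinearFilter(taus=np.array([0.0]), h=np.array([0.0]), dt=0.25),
            nonlin_rt=StaticNonlinearity("constant", {"rate": 0.3}),
        )
        pred = predict_response(model, stim)[RUN_TO_TURN]
        np.testing.assert_allclose(pred.p, 1.0 - np.exp(-0.3 * 0.25))

    def test_repulsive_step_response_shapes(self):
        stim = make_step(60.0, 0.25, [30.0], initial=-1)
        for shape, sustained in (("monophasic", True), ("biphasic", False)):
            gt = default_ground_truth(f"repulsive-{shape}")
            pred = predict_response(gt.as_ln_model(), stim)[RUN_TO_TURN]
            i_on = 120
            pre = pred.p[i_on - 20 : i_on].mean()
            transient = pred.p[i_on : i_on + 16].max()
            late = pred.p[-8:].mean()
            assert transient > pre  # rise after the step
            if sustained:
                assert late > pre + 0.5 * (transient - pre)
            else:
                assert late < pre + 0.25 * (transient - pre)  # relaxation

    def test_probabilities_in_unit_interval(self, small_population, bernoulli_stim):
        gt, _ = small_population
        for trace in predict_response(gt.as_ln_model(), bernoulli_stim).values():
            assert (trace.p >= 0).all() and (trace.p <= 1).all()

    def test_incomplete_model_rejected(self):
        stim = generate_bernoulli(10.0, 0.25, 0.5, seed=1)
        with pytest.raises(InvalidArgumentError):
            predict_response(LNModel(), stim)


class TestEmpiricalPSTH:
    def test_single_animal_single_event(self):
        states = np.array([0, 0, 1, 1, 0], dtype=np.int8)
        track = StateTrack("a", 0.0, 0.25, states)
        psth = empirical_psth([track], [0.0], (0.0, 1.0), RUN_TO_TURN)
        # new TURN state begins at t = 0.5
        i = np.flatnonzero(np.isclose(psth.times, 0.5))[0]
        assert psth.p[i] == 1.0
        assert psth.k.sum() == 1

    def test_flat_under_constant_hazard(self):
        stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=40)
        model = constant_hazard_model(0.2, 0.5)
        tracks = simulate_population(model, stim, 300, seed=40)
        psth = empirical_psth(tracks, [600.0], (-5.0, 5.0), RUN_TO_TURN)
        expected = 1.0 - np.exp(-0.2 * 0.25)
        se = np.sqrt(expected * (1 - expected) / psth.n)
        assert np.all(np.abs(psth.p - expected) < 4 * se)

    def test_counts_bookkeeping(self, small_population):
        _, tracks = small_population
        psth = empirical_psth(tracks, [100.0, 200.0], (-2.0, 2.0), TURN_TO_RUN)
        assert np.all(psth.k <= psth.n)
        assert np.all(psth.n <= 2 * len(tracks))

    def test_empty_at_risk_raises(self):
        track = StateTrack("a", 0.0, 0.25, np.zeros(20, dtype=np.int8))
        with pytest.raises(EmptyResultError):
            empirical_psth([track], [2.0], (-1.0, 1.0), TURN_TO_RUN)


class TestSelfConsistency:
    def test_prediction_matches_fresh_simulation(self):
        # fit on Bernoulli data, predict held-out step and pulse stimuli
        from scipy import stats as sps

        from optorc import (
            extract_transitions,
            filter_from_ta,
            make_pulse_train,
            triggered_average,
        )

        stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=50)
        gt = default_ground_truth("repulsive-biphasic")
        tracks = simulate_population(gt, stim, 200, seed=50)
        events = [e for tr in tracks for e in extract_transitions(tr)]
        ta = triggered_average(events, stim, RUN_TO_TURN, 4.0)
        filt = filter_from_ta(ta, ta.n_events / len(tracks), 1200.0)
        nonlin = estimate_nonlinearity(
            linear_predict(filt, stim), tracks, RUN_TO_TURN, 20, "sigmoid"
        )
        model = LNModel(filter_rt=filt, nonlin_rt=nonlin)

        step = make_step(120.0, 0.25, [30.0, 60.0, 90.0], initial=-1)
        pulse = make_pulse_train(120.0, 0.25, [0.5, 1, 2, 4] * 4, ([3, 3, 3, 6] * 4)[:15])
        in_band = []
        for held_out, n_fresh, seed in ((step, 120, 1050), (pulse, 240, 2050)):
            fresh = simulate_population(gt, held_out, n_fresh, seed=seed)
            pred = predict_response(model, held_out)[RUN_TO_TURN]
            t0 = fresh[0].t0
            psth = empirical_psth(
                fresh, [t0], (0.0, held_out.duration - t0 - 0.25), RUN_TO_TURN
            )
            idx = np.round((psth.times + t0 - pred.times[0]) / 0.25).astype(int)
            ok = (idx >= pred.n_burnin) & (psth.n >= 5)
            k, n, p = psth.k[ok], psth.n[ok], pred.p[idx[ok]]
            lo = np.where(k == 0, 0.0, sps.beta.ppf(0.025, k, n - k + 1))
            hi = np.where(k == n, 1.0, sps.beta.ppf(0.975, k + 1, n - k))
            in_band.append((p >= lo) & (p <= hi))
        assert np.concatenate(in_band).mean() >= 0.9
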