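"""Property-based validation suite.

Each function recomputes one end-to-end property of the toolchain from
scratch — generating stimuli, simulating populations from known ground
truth, running the estimators, and measuring agreement — and returns a
dictionary of metrics.  The test suite asserts thresholds on these
metrics; the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .events import RUN_TO_TURN, TransitionEvent, deceleration_onset, extract_transitions
from .errors import NotFoundError, InvalidArgumentError
from .lnmodel import (
    EmpiricalPSTH,
    LNModel,
    empirical_psth,
    estimate_nonlinearity,
    linear_predict,
    predict_response,
)
from .revcorr import LinearFilter, filter_from_ta, triggered_average
from .simulate import GroundTruthLN, SpeedModel, default_ground_truth, simulate_population
from .stats import psth_vs_baseline, two_proportion_ztest
from .stimulus import StimulusTrain, autocorrelation, generate_bernoulli, make_pulse_train, make_step
from .lnmodel import StaticNonlinearity

__all__ = [
    "autocorrelation_whiteness",
    "filter_recovery",
    "nonlinearity_recovery",
    "ln_self_consistency",
    "oracle_equivalences",
    "dynamics_ordering",
    "null_calibration",
    "deceleration_recovery",
]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def constant_hazard_model(rate_rt: float, rate_tr: float, dt: float = 0.25) -> GroundTruthLN:
    zero = np.array([0.0])
    return GroundTruthLN(
        filter_rt=LinearFilter(taus=np.array([0.0]), h=zero, dt=dt),
        filter_tr=LinearFilter(taus=np.array([0.0]), h=zero, dt=dt, kind="TURN_TO_RUN"),
        nonlin_rt=StaticNonlinearity("constant", {"rate": rate_rt}),
        nonlin_tr=StaticNonlinearity("constant", {"rate": rate_tr}),
    )


def naive_triggered_average(events, stim: StimulusTrain, kind: str, window: float):
    """Brute-force double-loop oracle for the event-triggered average."""
    n_lags = int(round(window / stim.dt)) + 1
    rows = []
    for ev in events:
        if ev.kind != kind:
            continue
        k = stim.index_at(ev.time)
        if k - (n_lags - 1) < 0 or k >= stim.n_samples:
            continue
        rows.append([float(stim.values[k + lag]) for lag in range(-(n_lags - 1), 1)])
    rows = np.asarray(rows)
    return rows.mean(axis=0), rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0])


# -- criterion 1: white-noise premise ----------------------------------------

def autocorrelation_whiteness(seed: int, n_seeds: int = 100, n_samples: int = 48000):
    """Fraction of nonzero lags (<= 5 s) of Bernoulli trains outside the
    3/sqrt(n) band, over ``n_seeds`` independent trains."""
    bound = 3.0 / np.sqrt(n_samples)
    violations = 0
    total = 0
    for s in _seeds(seed, n_seeds):
        train = generate_bernoulli(n_samples * 0.25, 0.25, 0.5, seed=s)
        ac = autocorrelation(train, 5.0)
        violations += int(np.sum(np.abs(ac[1:, 1]) > bound))
        total += ac.shape[0] - 1
    return {"violation_fraction": violations / total, "n_lags": total}


# -- criterion 2: filter recovery --------------------------------------------

def filter_recovery(seed: int, n_animals: int = 200, duration: float = 1200.0):
    """Estimate the run-to-turn filter from simulated populations of each
    ground-truth class; report Pearson r against truth and peak-lag error."""
    out = {}
    for kind_seed, kind in zip(_seeds(seed, 4), (
        "attractive-monophasic", "attractive-biphasic",
        "repulsive-monophasic", "repulsive-biphasic",
    )):
        stim = generate_bernoulli(duration, 0.25, 0.5, seed=kind_seed)
        gt = default_ground_truth(kind)
        tracks = simulate_population(gt, stim, n_animals, seed=kind_seed)
        events = [e for tr in tracks for e in extract_transitions(tr)]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=4.0)
        filt = filter_from_ta(ta, ta.n_events / n_animals, duration)
        truth = np.zeros_like(filt.h)
        truth[: gt.filter_rt.h.size] = gt.filter_rt.h
        r = float(np.corrcoef(filt.h, truth)[0, 1])
        peak_est = float(filt.taus[np.argmax(np.abs(filt.h))])
        peak_true = float(gt.filter_rt.taus[np.argmax(np.abs(gt.filter_rt.h))])
        out[kind] = {
            "pearson_r": r,
            "peak_lag_error_s": abs(peak_est - peak_true),
            "n_events": ta.n_events,
        }
    return out


# -- criterion 3: nonlinearity recovery --------------------------------------

def nonlinearity_recovery(seed: int, n_animals: int = 300, duration: float = 1200.0):
    """Recover known sigmoid and linear nonlinearities from simulation
    (>= 10^6 at-risk bins); report relative parameter errors."""
    s_sig, s_lin = _seeds(seed, 2)
    base = default_ground_truth("repulsive-monophasic")
    out = {}

    sig_truth = {"floor": 0.02, "amplitude": 0.25, "slope": 3.0, "midpoint": 0.3}
    gt = GroundTruthLN(
        base.filter_rt, base.filter_tr,
        StaticNonlinearity("sigmoid", sig_truth), base.nonlin_tr,
    )
    stim = generate_bernoulli(duration, 0.25, 0.5, seed=s_sig)
    tracks = simulate_population(gt, stim, n_animals, seed=s_sig)
    drive = linear_predict(gt.filter_rt, stim)
    fit = estimate_nonlinearity(drive, tracks, RUN_TO_TURN, n_bins=20, form="sigmoid")
    n_at_risk = int(sum((tr.states[:-1] == 0).sum() for tr in tracks))
    out["sigmoid"] = {
        "slope_rel_error": abs(fit.params["slope"] - sig_truth["slope"]) / sig_truth["slope"],
        "midpoint_rel_error": abs(fit.params["midpoint"] - sig_truth["midpoint"])
        / sig_truth["midpoint"],
        "n_at_risk_bins": n_at_risk,
        "r_squared": fit.goodness,
    }

    lin_truth = {"intercept": 0.4, "gain": 0.25}
    gt = GroundTruthLN(
        base.filter_rt, base.filter_tr,
        StaticNonlinearity("linear", lin_truth), base.nonlin_tr,
    )
    stim = generate_bernoulli(duration, 0.25, 0.5, seed=s_lin)
    tracks = simulate_population(gt, stim, n_animals, seed=s_lin)
    drive = linear_predict(gt.filter_rt, stim)
    fit = estimate_nonlinearity(drive, tracks, RUN_TO_TURN, n_bins=20, form="linear")
    out["linear"] = {
        "intercept_rel_error": abs(fit.params["intercept"] - lin_truth["intercept"])
        / lin_truth["intercept"],
        "gain_rel_error": abs(fit.params["gain"] - lin_truth["gain"]) / lin_truth["gain"],
        "n_at_risk_bins": int(sum((tr.states[:-1] == 0).sum() for tr in tracks)),
        "r_squared": fit.goodness,
    }
    return out


# -- criterion 4: LN predictive self-consistency ------------------------------

def _binomial_band_coverage(psth: EmpiricalPSTH, pred, t0: float, min_n: int = 5):
    idx = np.round((psth.times + t0 - pred.times[0]) / 0.25).astype(int)
    ok = (idx >= pred.n_burnin) & (psth.n >= min_n)
    k, n, p = psth.k[ok], psth.n[ok], pred.p[idx[ok]]
    lo = np.where(k == 0, 0.0, sps.beta.ppf(0.025, k, n - k + 1))
    hi = np.where(k == n, 1.0, sps.beta.ppf(0.975, k + 1, n - k))
    return (p >= lo) & (p <= hi)


def ln_self_consistency(seed: int, n_fit: int = 200, kind: str = "repulsive-biphasic"):
    """Fit an LN model on Bernoulli-stimulated simulated data; predict
    run-to-turn responses to held-out step and pulse-train stimuli and
    report the fraction of bins inside the 95% binomial band of fresh
    simulations (step: 120 animals; pulses: 240 animals)."""
    s_fit, s_step, s_pulse = _seeds(seed, 3)
    stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=s_fit)
    gt = default_ground_truth(kind)
    tracks = simulate_population(gt, stim, n_fit, seed=s_fit)
    events = [e for tr in tracks for e in extract_transitions(tr)]
    ta = triggered_average(events, stim, RUN_TO_TURN, window=4.0)
    filt = filter_from_ta(ta, ta.n_events / n_fit, 1200.0)
    nonlin = estimate_nonlinearity(
        linear_predict(filt, stim), tracks, RUN_TO_TURN, n_bins=20, form="sigmoid"
    )
    model = LNModel(filter_rt=filt, nonlin_rt=nonlin)

    step = make_step(120.0, 0.25, [30.0, 60.0, 90.0], initial=-1)
    pulse = make_pulse_train(120.0, 0.25, [0.5, 1, 2, 4] * 4, ([3, 3, 3, 6] * 4)[:15])
    in_band = {}
    for name, held_out, n_fresh, s in (
        ("step", step, 120, s_step),
        ("pulse", pulse, 240, s_pulse),
    ):
        fresh = simulate_population(gt, held_out, n_fresh, seed=s)
        pred = predict_response(model, held_out)[RUN_TO_TURN]
        t0 = fresh[0].t0
        psth = empirical_psth(
            fresh, [t0], (0.0, held_out.duration - t0 - 0.25), RUN_TO_TURN
        )
        in_band[name] = _binomial_band_coverage(psth, pred, t0)
    pooled = np.concatenate(list(in_band.values()))
    return {
        "coverage": float(pooled.mean()),
        "coverage_step": float(in_band["step"].mean()),
        "coverage_pulse": float(in_band["pulse"].mean()),
        "n_bins": int(pooled.size),
        "fit_r_squared": nonlin.goodness,
    }


# -- criterion 5: oracle equivalences -----------------------------------------

def oracle_equivalences(seed: int):
    """Triggered average vs double-loop oracle; z^2 vs chi-square; and
    constant-hazard bout durations vs the geometric closed form."""
    s_ta, s_z, s_ks = _seeds(seed, 3)

    stim = generate_bernoulli(50.0, 0.25, 0.5, seed=s_ta)
    rng = np.random.default_rng(s_ta)
    times = np.sort(rng.uniform(4.0, 49.0, size=10)).tolist()
    events = [TransitionEvent("a", t, RUN_TO_TURN) for t in times]
    ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
    mean_o, sem_o = naive_triggered_average(events, stim, RUN_TO_TURN, 2.0)
    ta_diff = float(max(np.abs(ta.mean - mean_o).max(), np.abs(ta.sem - sem_o).max()))

    rng = np.random.default_rng(s_z)
    max_z_chi_diff = 0.0
    for _ in range(200):
        n1, n2 = rng.integers(5, 200, size=2)
        k1 = int(rng.integers(0, n1 + 1))
        k2 = int(rng.integers(0, n2 + 1))
        if (k1 + k2) in (0, n1 + n2):
            continue
        z, _ = two_proportion_ztest(k1, int(n1), k2, int(n2))
        chi2 = sps.chi2_contingency(
            np.array([[k1, n1 - k1], [k2, n2 - k2]]), correction=False
        ).statistic
        max_z_chi_diff = max(max_z_chi_diff, abs(z**2 - chi2))

    stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=s_ks)
    tracks = simulate_population(constant_hazard_model(0.25, 0.25), stim, 800, seed=s_ks)
    durations = []
    for tr in tracks:
        change = np.flatnonzero(np.diff(tr.states) != 0) + 1
        bounds = np.concatenate([[0], change, [tr.states.size]])
        for lo, hi in zip(bounds[1:-2], bounds[2:-1]):
            if tr.states[lo] == 0:
                durations.append(hi - lo)
    durations = np.asarray(durations)
    p = 1.0 - np.exp(-0.25 * 0.25)
    rng = np.random.default_rng(s_ks)
    u = sps.geom.cdf(durations - 1, p) + rng.random(durations.size) * sps.geom.pmf(durations, p)
    ks_p = float(sps.kstest(u, "uniform").pvalue)
    return {
        "ta_oracle_max_abs_diff": ta_diff,
        "z2_chi2_max_abs_diff": float(max_z_chi_diff),
        "holding_time_ks_pvalue": ks_p,
        "n_bouts": int(durations.size),
    }


# -- criterion 6: dynamics ordering -------------------------------------------

def dynamics_ordering(seed: int, n_animals: int = 120):
    """Significance onset/offset of the step response for monophasic vs
    biphasic repulsive models (sustained-significance summaries, 2 bins)."""
    duration = 1200.0
    switches = [t for c in range(30) for t in (c * 40.0 + 20.0, c * 40.0 + 40.0)
                if t < duration]
    stim = make_step(duration, 0.25, switches, initial=-1)
    aligns = [c * 40.0 + 20.0 for c in range(1, 29)]
    out = {}
    for s, kind in zip(_seeds(seed, 2), ("repulsive-monophasic", "repulsive-biphasic")):
        gt = default_ground_truth(kind)
        pop = simulate_population(gt, stim, n_animals, seed=s)
        psth = empirical_psth(pop, aligns, (-5.0, 15.0), RUN_TO_TURN)
        pre = psth.times < 0
        baseline = (int(psth.k[pre].sum()), int(psth.n[pre].sum()))
        post = psth.times >= 0
        trace = psth_vs_baseline(
            EmpiricalPSTH(times=psth.times[post], p=psth.p[post],
                          n=psth.n[post], k=psth.k[post], kind=psth.kind),
            baseline,
        )
        out[kind] = {
            "onset_s": trace.onset_time(sustain=2),
            "offset_s": trace.offset_time(sustain=2),
        }
    return out


# -- criterion 7: null calibration --------------------------------------------

def null_calibration(seed: int, n_seeds: int = 100, n_ztest_bins: int = 10**4):
    """Flat triggered averages under stimulus-independent transitions
    (fraction of lags outside +/- 2 SEM) and z-test false-positive rate
    under the null."""
    outside = 0
    total = 0
    for s in _seeds(seed, n_seeds):
        stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=s)
        tracks = simulate_population(constant_hazard_model(0.25, 0.25), stim, 3, seed=s)
        events = [e for tr in tracks for e in extract_transitions(tr)]
        ta = triggered_average(events, stim, RUN_TO_TURN, window=2.0)
        outside += int(np.sum(np.abs(ta.mean) > 2 * ta.sem))
        total += ta.mean.size

    rng = np.random.default_rng(_seeds(seed + 1, 1)[0])
    n1, n2, p_true = 500, 2000, 0.1
    k1 = rng.binomial(n1, p_true, size=n_ztest_bins)
    k2 = rng.binomial(n2, p_true, size=n_ztest_bins)
    hits = sum(
        two_proportion_ztest(int(a), n1, int(b), n2)[1] < 0.05
        for a, b in zip(k1, k2)
    )
    return {
        "ta_outside_2sem_fraction": outside / total,
        "ztest_false_positive_rate": hits / n_ztest_bins,
        "n_lags": total,
        "n_ztest_bins": n_ztest_bins,
    }


# -- criterion 8: deceleration timing ------------------------------------------

def deceleration_recovery(seed: int, n_animals: int = 10, decel_lead: float = 1.0):
    """Mean recovered deceleration-onset time over >= 10^3 simulated
    run-to-turn transitions with a known deceleration lead."""
    s = _seeds(seed, 1)[0]
    stim = generate_bernoulli(1200.0, 0.25, 0.5, seed=s)
    gt = default_ground_truth("attractive-monophasic")
    tracks = simulate_population(
        gt, stim, n_animals, seed=s, speed_model=SpeedModel(decel_lead=decel_lead)
    )
    onsets = []
    for tr in tracks:
        for ev in extract_transitions(tr):
            if ev.kind != RUN_TO_TURN:
                continue
            try:
                onsets.append(deceleration_onset(tr, ev, window=2.0))
            except (NotFoundError, InvalidArgumentError):
                continue
    onsets = np.asarray(onsets)
    return {
        "mean_onset_s": float(onsets.mean()),
        "mean_abs_error_s": float(abs(onsets.mean() + decel_lead)),
        "n_transitions": int(onsets.size),
    }
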