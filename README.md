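# optorc

Reverse-correlation and linear–nonlinear (LN) modelling of two-state
(run/turn) navigation behavior under binary optogenetic stimulation.

The package treats a freely behaving animal as a transducer: a ±1
Bernoulli light sequence drives the hazards of switching between two
motor states (RUN and TURN). Event-triggered stimulus averages estimate
the linear filters of the transition hazards; a static nonlinearity
(sigmoid or line) fitted by least squares completes an LN model that
predicts per-bin transition probabilities for arbitrary stimulus
waveforms (steps, pulse trains, flicker). A ground-truth LN simulator
generates synthetic populations so the whole chain is testable
end-to-end without any external data.

## Modules

| module | contents |
|---|---|
| `optorc.stimulus` | ±1 stimulus trains on a 4 Hz clock: Bernoulli white noise, steps, pulse trains, autocorrelation |
| `optorc.simulate` | ground-truth LN two-state simulator (`simulate_population`), four named ground-truth classes, speed traces with a pre-turn deceleration ramp |
| `optorc.events`   | transition extraction, standard-scored speed, deceleration-onset detection |
| `optorc.revcorr`  | event-triggered averages (mean ± SEM) and the rate-scaled linear filters derived from them |
| `optorc.lnmodel`  | convolution prediction, static-nonlinearity estimation, LN prediction, empirical PSTHs |
| `optorc.stats`    | two-proportion z-tests vs baseline, per-lag Welch t-tests vs control, significance onset/offset summaries |
| `optorc.validation` | the property-based acceptance computations (recovery, calibration, self-consistency) |
| `optorc.cli` / `optorc.pipeline` | `optorc` command-line interface and the end-to-end pipeline |

All artifacts are plain text: CSV for stimuli, tracks, events, triggered
averages, PSTHs and significance tables; JSON for filters and models
(see `optorc.io` for the column dictionaries).

## Command-line usage

```sh
# 20 min of 4 Hz Bernoulli stimulation
optorc stim bernoulli --duration 1200 --seed 1 --out stim.csv

# a synthetic population from a named ground-truth model
optorc ground-truth --kind repulsive-biphasic --out gt.json
optorc simulate --model gt.json --stim stim.csv --n-animals 120 --seed 1 --out tracks.csv

# full pipeline: events -> triggered averages -> filters -> nonlinearity -> predictions
optorc fit --tracks tracks.csv --stim stim.csv --out-dir results/

# predict the response to a step stimulus with the fitted model
optorc stim step --duration 120 --switch 30 --switch 60 --switch 90 --out step.csv
optorc predict --model results/model.json --stim step.csv --out pred.csv

# one-shot demo (simulation + pipeline)
optorc demo --out-dir demo/
```

Individual stages are also available as `optorc events`, `optorc
revcorr`, `optorc psth`, `optorc ztest` and `optorc ttest`.

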