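# seqtrack

Analysis of dorsomedial-striatum (DMS) single-unit spiking during
fixed-length lever-press sequences. In the FS5 task a rat must make at least
five consecutive lever presses before entering the reward port; premature
entries reset the requirement. DMS population activity evolves across such
sequences in a ramp-like pattern, so the animal's *progress* through the
sequence — and whether a sequence will be completed at all — can be read out
from firing rates. `seqtrack` is a tested, reusable implementation of that
analysis chain for anyone working with operant event logs plus sorted spike
times: behavioral parsing, cell-type classification, spike-train time
warping, population characterization, and cross-validated decoding, together
with a ground-truth synthetic generator used to validate every estimator.

## The analysis in brief

* **Parsing** — event streams (`lever_press`, `port_entry`,
  `reward_delivery`) become sequence trials; complete = ≥ 5 presses and
  rewarded; trials with sequences > 20 s or port-entry latency > 10 s are
  excluded.
* **Unit classification** — putative MSN / FSI / TAN / excluded-intermediate
  from mean rate, waveform half-valley width, and ISI CV (e.g. FSI: > 20 Hz
  and < 0.15 ms).
* **Relative-time warping** — spike times between the first and last press
  are divided by the sequence duration and binned into 100 bins (Hz); the
  port approach gets 25 bins; 1-s lever-approach and reward windows get 25
  real-time bins each. The concatenated 175-bin trace is smoothed with a
  causal half-normal kernel (σ = 5 bins) and z-scored:
  `z_i = (F_i − F_mean)/F_sd`.
* **Population** — PCA score time courses (time bins as observations,
  neurons as variables), excited/inhibited splits, complete-vs-incomplete
  modulation contrasts, per-interval quartile groups.
* **Decoding** — linear discriminant (Ledoit–Wolf–shrunk covariance) or
  random-forest classification of (i) which of K = 5 relative-time intervals
  a firing-rate sample comes from (26 trials, leave-one-trial-out CV,
  pseudo-ensembles of units pooled across sessions) and (ii) whether a trial
  is complete or incomplete from single-epoch rates (10 + 10 trials, 10-fold
  CV, 100 repeats). Box-Cox normalization of predictors; chance from label
  shuffles; one-sided permutation p-values; McNemar χ² = (b−c)²/(b+c) for
  paired decoder fractions.

See `docs/methods.md` for assumptions, parameter defaults, and design
decisions.

## Worked example

Generate a synthetic session, parse it, and decode sequence progress:

```python
import numpy as np
from seqtrack import behavior, decode, synth, substream

bcfg = synth.BehaviorGenConfig(n_trials=45, p_complete=0.85, seed=7)
ucfg = synth.UnitGenConfig(n_units=110, seed=7)
exp = synth.simulate_experiment(bcfg, ucfg)

trials = behavior.parse_events(exp.event_log)
summary = behavior.behavioral_metrics(trials)
print(f"{summary.percent_complete:.1f}% complete")

complete = [t for t in trials if t.valid and t.complete]
tables = {
    u: decode.build_interval_features(complete, s, 5, 26, substream(7, "t", u))
    for u, s in exp.spikes.items()
}
tables, _ = decode.exclude_sparse_units(tables)
runs = decode.decode_intervals_ensemble(
    tables, decode.DecodeConfig(), substream(7, "e"),
    ensemble_sizes=[10, 50], draws_per_size=5,
)
acc = decode.summarize_ensemble_runs(runs).groupby("ensemble_size")["overall_accuracy"].mean()
print(acc.round(3))
```

prints

```
82.2% complete
ensemble_size
10    0.646
50    0.935
Name: overall_accuracy, dtype: float64
```

82.2% of parsed trials are complete (the generator plants 85%), and interval
decoding accuracy rises with pseudo-ensemble size — chance is 0.2, a
10-unit ensemble reaches ~0.65, a 50-unit ensemble ~0.94, with the first and
last intervals decoded best (the signature of ramping activity).

The same stages are available from the shell:

```sh
seqtrack simulate --seed 7 --out session/
seqtrack behavior --events session/events.csv --out summary.txt
seqtrack classify-units --spikes session/spikes.csv --meta session/unit_meta.csv --out labels.csv
seqtrack warp --events session/events.csv --spikes session/spikes.csv --out matrix.csv
seqtrack pca --matrix matrix.csv --out pca.csv
seqtrack decode-intervals --events session/events.csv --spikes session/spikes.csv --seed 7 --out decode/
seqtrack decode-outcome --events session/events.csv --spikes session/spikes.csv --seed 7 --out outcome.csv
```

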