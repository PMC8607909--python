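# Methods

`seqtrack` analyzes single-unit spiking recorded in dorsomedial striatum (DMS)
while a rat performs a fixed-sequence operant task (FS5): a reward requires at
least five consecutive lever presses before the first port entry, a premature
entry resets the requirement, and presses beyond the fifth are consequence-free
parts of the same complete sequence. The package implements the full analysis
chain on top of parsed spike times and behavioral event logs, and ships a
ground-truth generator so every estimator can be validated by recovery tests.

## Behavioral parsing

A session is a time-ordered stream of `lever_press`, `port_entry` and
`reward_delivery` events. Every maximal run of presses terminated by a port
entry is one trial; a trial is *complete* when it has ≥ 5 presses and is
rewarded, *incomplete* otherwise. Trials whose press sequence exceeds 20 s or
whose port-entry latency exceeds 10 s are flagged invalid and excluded from
analysis.

Decisions where the event semantics are underdetermined:

* **LP1-latency anchor.** Latency to the first press is measured from the
  preceding port entry (session start for the first trial), matching the trial
  cycle of the task.
* **Reward attribution.** A `reward_delivery` within 0.5 s of a port entry
  marks that trial rewarded; this tolerates logging-order jitter.
* **Truncated runs.** A trailing press run with no terminating port entry is
  emitted with `valid=False, invalid_reason="truncated"` rather than silently
  dropped, so the press-partition invariant (every press belongs to exactly one
  trial) holds.
* Port entries with no preceding press produce no trial; a warning count is
  logged.

## Unit classification

Units are labeled from three scalars — session-wide mean rate (Hz),
half-valley width of the mean waveform (ms), and ISI coefficient of variation:
FSI if rate > 20 Hz and width < 0.15 ms; TAN if rate < 5 Hz, width > 0.45 ms
and CV < 1; otherwise excluded-intermediate if rate ∈ [12.5, 20] Hz or width
∈ [0.4, 0.45] ms; otherwise MSN. Interneuron rules take precedence over the
intermediate exclusion. Inequalities are applied literally (closed intervals
for the intermediate bands); boundaries have measure zero for real metrics.
Units with fewer than three spikes have no defined CV and are flagged
unclassifiable. No quantitative "well-defined waveform" criterion is applied;
users must pre-filter sorter output themselves.

## Relative-time warping

Trial durations vary, so sequence activity is expressed in relative time:
spike times between the first (LP1) and last (LLP) press are divided by the
sequence duration and binned into **100** equal bins; counts are divided by
the real bin duration to give Hz. The port approach (LLP → port entry) is
warped the same way onto **25** bins. The 1-s lever-approach window before LP1
and the 1-s reward window after the port entry use **25** real-time bins of
40 ms. Concatenation gives a **175-bin** trace (lever approach | sequence |
port approach | reward).

Numerical conventions:

* Bins are half-open `[lo, hi)`; a spike exactly at LLP (or at the port entry
  for the approach warp) falls in the final bin, so counts are conserved
  exactly.
* Smoothing uses a half-normal kernel (σ = 5 bins) truncated at 3σ (16 taps,
  < 1% mass lost) and renormalized. It is applied **causally** (output bin i
  mixes bins ≤ i only): the half-normal's non-negative support implies a
  one-sided kernel, and the direction is configurable (`WarpConfig.causal`).
  The leading edge is renormalized over the available taps so a constant input
  stays exactly constant.
* z-scoring is `(F_i − F_mean)/F_sd` with the population SD across the 175
  bins, so every non-degenerate trace has mean 0 and SD 1 to machine
  precision. Constant traces (F_sd = 0) are flagged degenerate and excluded
  downstream.
* Per-unit traces are built by warping each trial, averaging the **raw** rates
  across trials, then smoothing and z-scoring the average — this matches
  per-neuron population heatmaps and stabilizes F_sd.
* Incomplete trials are warped identically over their own (shorter) span.

A unit is *excited* if its mean z over the sequence bins is > 0, *inhibited*
otherwise (an exact zero ties to inhibited).

**Event-centered variant.** Rates in 40-ms bins over ±0.4 s around six
events — LP1, LP2, one seeded-random intermediate press, the second-to-last
press, LLP, and the port entry — give a 6 × 20 = **120-bin** vector, smoothed
and z-scored as above. Descriptions of this analysis elsewhere are internally
inconsistent about the total bin count (a 160-bin figure appears alongside a
6-events × 20-bins structure); we implement the 6 × 20 core and document the
discrepancy rather than guess at extra flanks.

## Population characterization

The population matrix stacks z-scored trial-averaged traces (units × 175).
PCA treats **time bins as observations and neurons as variables** (the matrix
transpose), centering columns and applying no re-scaling since rows are
already z-scored; the first components' score time courses and percent
variance are reported. Group traces report mean ± SEM **across units**.

**Complete-vs-incomplete contrast.** For each unit the smoothed condition
averages are compared on the sequence segment. Each condition's trace is
centered on its own mean (removing baseline offsets) and **both are scaled by
the complete-trial SD**. This choice is deliberate: scaling each condition by
its own SD makes the measure invariant to a uniform scaling of the modulation
profile, i.e. structurally blind to a multiplicative attenuation — exactly the
effect of interest. With the shared scale, the reported `attenuation`
(|z_complete| − |z_incomplete| over sequence bins) is positive in expectation
whenever incomplete-trial modulation is weaker, and the `gain_ratio` (the
no-intercept regression slope of the incomplete on the complete
sequence-segment deviations) estimates the attenuation factor g directly.
The excited/inhibited split always uses complete-trial labels, including when
summarizing incomplete traces. Units need ≥ 5 trials per condition and a
non-constant complete-trial trace. Note that per-unit sign detection is
statistically weaker for inhibited units: downward modulation is bounded by
rate non-negativity, so its amplitude (≤ the baseline) is smaller than an
excited unit's at the same gain; group-level attenuation remains positive for
both groups.

**Quartile groups.** Per sequence interval, units below the lower / above the
upper quartile of the interval mean-z distribution are Inh / Exc, the rest
Mid; inequalities are strict, so boundary ties fall to Mid and an all-equal
distribution is entirely Mid. Output ordering is stabilized by unit id.

## Decoding

**Interval decoding.** Each complete trial's sequence is cut into K equal
consecutive relative-time intervals (K ∈ {3, 5, 7}; default 5); the feature
of a sample (trial, interval) is each unit's rate in that interval. Only
sessions with ≥ 26 eligible complete trials participate; 26 trials are drawn
per unit (seeded). Pseudo-ensembles pool separately recorded units after
independently permuting each unit's trials, destroying spurious within-session
correlations symmetrically. Cross-validation is leave-one-trial-out (26
folds ≈ train on 95%); per-interval accuracies are fold-averaged. Units with
zero rates in > 75% of trial × interval cells are excluded. Ensemble sizes
default to 10/50/100/500/900 with 50 draws per size; single-unit decoding
averages 26-fold accuracy over 20 trial re-draws.

**Classifier.** Linear discriminant analysis with pooled within-class
covariance estimated by Ledoit–Wolf analytic shrinkage (always on — required
whenever features ≥ training samples per fold, e.g. 900 units × ~125 training
samples), plus a ridge floor of 1e-9·(mean variance + 1) that keeps the
discriminant defined when the within-class scatter is exactly singular
(noiseless synthetic data). This covariance treatment is the main numerical
divergence risk relative to other LDA implementations whose internal defaults
are unrecoverable, and is therefore surfaced here and in run manifests. A
random-forest variant mirrors the contract (500 trees, mtry = ⌊√p⌋).

**Box-Cox.** Predictors are Box-Cox transformed with per-feature
maximum-likelihood λ before the discriminant fit (LDA assumes normal
predictors). Zero rates are offset by half the feature's smallest positive
value; constant features are left untransformed and flagged. The transform is
fitted on the full feature table (it is label-free; nulls exploit this by
transforming once and re-permuting labels).

**Chance and significance.** The shuffle control permutes interval labels
(or complete/incomplete labels) per run; nulls default to 1000 runs. The
one-sided permutation p-value is (1 + #{null ≥ observed})/(1 + n).
Best-interval assignment: an interval is significant when the unit's accuracy
exceeds the 99th percentile of the pooled population's interval-shuffled
accuracies for that interval (pooling across the population, with a per-unit
variant exposed); the best interval is the significant one with maximal
accuracy, earliest on ties.

**Outcome decoding.** Scalar mean rate per unit per epoch — lever approach
[LP1−1 s, LP1), post-LP1 [LP1, LP1+0.5 s), pre-LLP [LLP−0.5 s, LLP), port
approach [LLP, PE) (equivalent to the mean of the 25 warped bins), reward
[PE, PE+1 s) — with 10 complete + 10 incomplete trials drawn per repeat,
stratified 10-fold CV, 100 repeats. Scalar (rather than bin-level) epoch
features keep n ≪ p sane; a bin-level flag is a possible extension. Units
all-zero in an epoch are dropped for that epoch.

**McNemar.** χ² = (b − c)²/(b + c) on paired discordant counts; continuity
correction off by default, available by flag; undefined (error) at b + c = 0.

All randomness flows from one master seed through named substreams
(`seqtrack.substream`), so every trial draw, ensemble draw, shuffle and fold
split is independently reproducible.

## Synthetic generator

The generator emulates the study conditions the analyses assume; its defaults
are the conditions used throughout the tests.

* **Behavior** — p(complete) 0.8 (a trained rat's asymptote; mid-training
  contrasts use 0.5), complete lengths {5..9} peaked at 5, incomplete {2..4};
  first IPI 1.4 s shrinking geometrically by ρ = 0.85 per position
  ("scalloping") with lognormal noise (σ = 0.25), giving 5-press sequences of
  ~4.5 s; LP1 latency ~lognormal, median 4 s + 2.5 s floor (the floor keeps
  the lever-approach and previous reward windows disjoint); port-entry latency
  ~1 s; incomplete trials are slowed 1.6× throughout. Optional session limits
  (duration, reward count) truncate trial generation.
* **Spiking** — inhomogeneous Poisson: intensity profiles are defined on the
  relative-time axis (flat; ramp up, baseline → baseline·(1+gain) across the
  sequence with a symmetric decay across the port approach; ramp down,
  bounded at 0.9·baseline of depth by rate non-negativity; phasic port-entry
  Gaussian transient, σ = 0.2 s) and mapped onto each trial's real-time
  landmarks via a piecewise-constant grid with 100 sub-bins across the
  sequence, so a warped recovery is exact in expectation and any residual bias
  is the estimator's own. Baseline 5 Hz, gain 3, rates rectified at 0.1 Hz.
  Incomplete trials multiply the modulation depth by the attenuation g.
* **Waveform metrics** — (rate, width, CV) triples drawn from class-typical
  regions at the recorded class mix MSN/FSI/TAN/intermediate =
  0.88/0.04/0.02/0.06; by construction each class's triples fall inside its
  own rule region, so classification-recovery tests check the rule logic, not
  distributional overlap.

What the generator does **not** emulate: across-session learning, electrode
drift, within-session correlated variability between simultaneously recorded
units (trials are conditionally independent given the behavior), bursty or
refractory ISI structure, and reward-consumption responses that exist only on
rewarded trials. Passing recovery tests therefore demonstrate estimator
correctness under the assumed model, not robustness to these real-data
features; in particular pseudo-ensemble decoding on real data additionally
rests on the independence assumption that pooling across sessions enforces.

## Problem sizes used in tests and the acceptance script

Test fixtures use a 45-trial session with 110 units (≥ 26 complete trials, as
the ensemble analyses require) and ensemble sizes 10/50/100 with 5 draws;
chance calibrations use 100 shuffle runs (1000 for the per-interval
permutation null); the attenuation study uses a mid-training session run to
the 30-reward session limit (~30 trials per condition) with 200 planted
excited units. These sizes were chosen to make the statistical assertions
well-powered while keeping the suite quick to iterate on; all are
configurable.

## Known limitations

* The smoothing direction (causal) and the LDA covariance treatment are
  documented choices, not uniquely determined by the analysis description
  they implement; both are configurable/visible.
* The event-centered vector length ambiguity (above).
* Box-Cox is fitted on the full table rather than per training fold; it is
  label-free, so no label leakage occurs, but fold-wise refitting would be
  stricter.
* `half_valley_width_from_waveform` is a convenience for sorter metadata
  gaps; it assumes a baseline-zeroed mean waveform with a negative trough.
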