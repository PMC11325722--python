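# Methods

This note documents the models, defaults and numerical choices behind
`oriens`, in the spirit of a package methods appendix.  It states no
empirical result that the test suite does not itself compute.

## Orientation space and channel basis

Orientations are axial (180°-periodic) and expressed in degrees at every
API boundary; 0° is vertical and positive angles are clockwise (the
rotation sign is a package convention — the underlying experiments are
symmetric under reflection, so nothing downstream depends on it).  The
canonical interval is `(-90, 90]`.

Channel tuning is `cos^7` of the wrapped orientation difference.
Because wrapping puts the difference in `(-90, 90]`, the cosine is
non-negative and no rectification rule is needed; the response is 1 at
the preferred orientation and 0 at ±90°.  Six channels at ±15°, ±45°,
±75° match the six stimulus orientations.  Basis size and exponent are
configurable but only the 6-channel cos^7 configuration is exercised by
the validation suite.

Set averages use the circular mean on doubled angles — the correct mean
for axial data.  For every built-in stimulus set it coincides with the
arithmetic mean, so the choice is observationally neutral for the
standard stimuli; it raises an explicit error for degenerate component
sets (balanced 0°/90°) instead of returning an arbitrary value.

## Synthetic data generator

Epochs follow the linear forward model `B = W C + noise`:

- **Weights** `W` (10 electrodes × 6 channels): standard-normal draws,
  redrawn on rank deficiency.  Each simulated participant gets their own
  `W`, mimicking idiosyncratic head geometry; the same `W` underlies a
  participant's single-orientation and ensemble sessions, which is what
  licenses cross-decoding.
- **Envelope**: stimulus-driven amplitude ramps up linearly over 50 ms
  from 80 ms, sustains, and ramps down over 100 ms from 800 ms.  The
  window loosely mirrors the decodable period observed in real data of
  this kind; it is a free default, not a claim.
- **Ensemble drive** (ensemble task): the channel drive at time t is
  `(1 − mix(t)) · mean_i C(component_i) + mix(t) · C(average + bias)`.
  `mix(t)` is a trapezoid: 0 outside the ensemble window (default
  400–700 ms), rising/falling over 100 ms ramps inside its edges.  The
  trapezoid — rather than a one-way ramp — keeps the ensemble drive
  strictly inside the window, which is the generator's planted ground
  truth for recovery tests and matches the modeled phenomenon (an
  ensemble representation that emerges and then fades).  A callable
  `mixture_weight` can override it, e.g. `mix ≡ 1` for ensemble-only
  simulations.
- **Noise**: per-electrode AR(1) Gaussian (φ = 0.5, stationary SD
  `noise_sd = 1`), independent across electrodes and trials.  AR(1) is
  the minimal temporally correlated choice that makes time-cluster
  inference meaningful.
- **Signal gain** 0.08 (default): single-trial SNR well below 1, as in
  real scalp EEG.  This matters beyond realism: with implausibly strong
  single-trial signal, label-permuted weight matrices become dominated
  by the (label-independent) mean evoked response, `ŴᵀŴ` turns
  ill-conditioned, and the inversion amplifies noise — inflating the
  permutation null of sensitivity far beyond the observed slope, which
  is bounded by the ideal value ≈ 0.0113.  At realistic SNR the null is
  well behaved.  (Scale-free statistics such as the brain–behavior
  correlation are insensitive to this, and some validation runs use
  gain 0.15 for sharper continuous decoding.)
- **Behavior linkage**: each participant has a clockwise perceptual
  bias drawn from N(0, 5°) (spread comparable to adjustment errors
  "mostly within ±10°" in this paradigm) that shifts both the ensemble
  drive (`average + bias`) and the behavioral reports
  (`average + bias + N(0, 8°)`), giving the correlation analysis a
  recoverable signal.  Reports from dummy sets, and reports whose sign
  contradicts the true average (including exactly 0°), are flagged
  excluded.
- Trial counts mirror the experimental design: 8 × 120 trials over six
  orientations, 4 × 120 over the four primary sets, 60 per set over all
  eight sets in the behavioral task.

Not emulated: volume conduction/realistic topographies, ocular or
muscular artifacts (the corresponding ICA-based cleaning step of real
pipelines is out of scope), response times, and any nonlinearity in the
EEG generation.  Passing tests therefore validate the *analysis* under
a linear, stationary-noise world; they cannot certify performance on
real recordings.

## Preprocessing

Zero-phase Butterworth band-pass (1–80 Hz), order 6, applied
forward–backward (`sosfiltfilt`), then integer decimation (1000 →
500 Hz by default; the 80 Hz cutoff provides anti-aliasing), then
per-trial per-electrode baseline subtraction over −300…0 ms.  Order 6
was chosen so the zero-phase cascade attenuates a 100 Hz tone by more
than 20 dB (order 4 reaches only ≈ 18 dB); zero-phase filtering is used
so decoding latencies are not biased by filter delay.

Class balancing undersamples to the minimum class count; trial
averaging partitions each class into n equal groups (default 5),
dropping remainder trials so every pseudo-trial averages the same
number of raw trials (equal pseudo-trial SNR).  Z-scoring uses
per-electrode mean/SD of the *training* partition pooled over trials
and samples in −300…900 ms; the test partition is transformed with the
training statistics only.  Sliding windows are 100 ms wide, stepped
every 2 ms by default over −300…900 ms (551 windows at 500 Hz); windows
cover samples `start ≤ t < start + width`.

All operations carry the trial table along, and honor a `keep` flag
standing in for manual trial rejection.

## Decoding analyses

**SVM path.** Per window, per repetition: undersample (redrawn each
repetition), average into 5 sets, 5-fold leave-one-set-out CV (12
training samples = 4 sets × 3 orientations, 3 test samples), z-score
within the fold, train a linear one-vs-rest SVM (`LinearSVC`, C = 1) on
spatiotemporal features (electrodes × in-window samples).  20
repetitions × 5 folds = 100 fold accuracies per window, all retained.
Prediction takes the highest of the three per-class decision values,
ties broken toward the lowest class; softmax (temperature 1) of the
decision values of each test sample gives 300 posterior values per
window, averaged to 3 probabilities per presented orientation.  Each
window's classifier is trained independently.

**IEM path.** Same balancing/averaging/CV scheme, but features are
window means (one per electrode) and all six orientations enter.  Per
fold, `C₁` has one column per training pseudo-trial (24 = 4 sets × 6
orientations), each column the basis response to that pseudo-trial's
orientation — this granularity preserves the CV structure.  `B₂` is
the per-condition mean of the ensemble task's window features (4
columns), transformed with the training fold's z-statistics.  The 100
fold × repetition estimates of `Ĉ₂` are averaged.  Inside the engine
the per-window estimates run as batched einsum/solve operations; the
public `estimate_weights`/`invert_channel_responses` implement the
identical algebra with conditioning checks (cond > 1e10 raises), and
the unit tests pin both to a generic least-squares oracle at 1e-10.

**Alignment and sensitivity.** Profiles are reindexed by wrapped offset
`center − average` into the order (−90, −60, −30, 0, +30, +60); offsets
are wrapped into [−90, 90) so the +90 ≡ −90 channel lands in the −90
slot.  The two conditions of a set type ("w"/"w/o") are aligned
individually, then averaged.  Sensitivity is the OLS slope of
(p(−90), p(−60), p(+60), p(−30), p(+30), p(0)) against
(−90, −60, −60, −30, −30, 0); the ideal cos^7 profile gives
≈ 0.01126 response units/degree.

**Continuous decoding** correlates a profile with the basis prediction
for the 180 integer-degree candidates (−89°…90°), restricted to the
sign of the true average (0° excluded, +90° counted positive);
correlation ties break toward the candidate closest to the true
average.  Deviations are formed by subtracting the true average — no
mirror flip — so a clockwise bias is positive for both +45° and −45°
sets and the conditions can be pooled.

## Statistics

One-tailed (upper) add-one permutation p-values:
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`.  Clusters are maximal
runs of windows with pointwise p below the cluster-defining threshold;
the null cluster-size distribution applies the same pointwise rule
within the null (each permutation ranked against all permutations,
self included) and records each permutation's **maximum** cluster size,
the standard max-statistic construction that controls family-wise error
over time.  Defaults: 0.05/0.05 for accuracy and sensitivity, 0.1/0.1
for the correlation analysis.  `n_perm` is configurable; validation
runs use 25–200 permutations (scaled down from the 1000 a full study
would use) — with add-one p-values the smallest attainable p is
1/(n_perm+1), so thresholds remain attainable at these sizes.

Sensitivity inference is group-level: the statistic is the mean
sensitivity across participants, and each permutation shuffles every
participant's training-task labels before recomputing the mean.
Single-dataset permutation nulls are intrinsically wider than the
bounded observed slope and have essentially no power — an instance of
the general point that this design's sensitivity statistic is a
group-level quantity.

The brain–behavior analysis correlates, across participants and per
window, the continuously decoded deviation (participant's own model,
averaged over the two conditions of a set type) with the mean
non-excluded behavioral deviation; windows with zero variance in either
variable are flagged undefined (NaN) rather than raising.  Its
permutation null refits every participant's IEM under label
permutation, re-decodes, and re-correlates.

## Pipeline

`run_pipeline` executes simulate → preprocess → decode → iem → stats,
expanding one global seed into independent per-stage streams (so
changing `n_perm` never perturbs the simulation draws), and writes CSV
and JSON artifacts plus a manifest with a config hash, stage timings
and SHA-256 checksums.  Result files are byte-identical across reruns
of the same config and seed.  `summarize_run` renders the recovered
clusters against the planted ensemble window.  The library functions
and the `examples/` scripts are the intended interface; the package
deliberately ships no shell entry point, as analyses of this kind are
driven from Python.

## Validation problem sizes

The study-level tests scale the analyses to desk size as their own
design choice: single analysis windows for calibration checks, 50 ms or
100 ms window steps instead of 2 ms, 5–10 cross-validation repetitions
instead of 20 where only averages matter, 6–12 simulated participants,
and 25–200 permutations.  Structural counts (100 folds, 12 training
samples, 300 posteriors, 180 candidates, 40-trial averaging sets, 551
windows) are asserted exactly at the canonical settings.

## Known limitations

- The generator's linearity means IEM recovery is exact up to noise by
  construction; the tests quantify the *procedure's* calibration and
  power, not the biological validity of the channel model.
- Orientation sensitivity is also positive while element-driven signal
  is present, because for these stimulus sets the mean element response
  itself peaks at the average orientation; the planted-window recovery
  experiments therefore use ensemble-only drive, and timing claims on
  real data rest on the correlation analysis, whose linkage is
  exclusive to the ensemble window.
- Epoching from continuous recordings, vendor file formats, ICA
  artifact removal and electrode-space clustering are out of scope.
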