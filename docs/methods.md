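# Methods

This package implements a complete analysis chain for detecting
stimulus-specific *replay* during working-memory maintenance in
multichannel oscillatory recordings, and for quantifying how strongly the
detected replay events couple to the phase of ongoing theta. Because raw
recordings of this kind are rarely shareable, the chain is validated
end-to-end on a synthetic cohort generator that plants known category
patterns, replay events and theta-coupling parameters, so that every
stage can be checked by parameter recovery rather than by eyeballing.

## 1. The analysis chain

### 1.1 Trial structure and conventions

Epochs are 9 s sampled at 480 Hz: a 1 s pre-stimulus margin, 3 s of
sample (stimulus) presentation, and a 5 s maintenance (delay) period.
All times are in milliseconds relative to sample onset; the maintenance
window is the half-open interval [3000, 8000) ms. Each of 8 subjects
contributes three task conditions (*control*, *nonconfigural*,
*configural*) with 20 indoor and 20 outdoor trials each; indoor trial
*i* is paired with outdoor trial *i* by presentation index.

### 1.2 Time-frequency decomposition (`timefreq`)

Single-trial spectral amplitude is the modulus of the complex
convolution with a Morlet wavelet

w(f, t) = (2π σ_t²)^(−1/2) · exp(−t²/(2σ_t²)) · exp(2πi f t),

with the constant ratio f/σ_f = 7 (σ_f = 1/(2π σ_t)), i.e. ~7 cycles
per wavelet. The analysis grid has 1 Hz steps over 2–20 Hz and 2 Hz
steps over 21–79 Hz (49 bins; 38 of them inside the 13–79 Hz classifier
band). Amplitude is baseline-normalized per trial, sensor and frequency
by subtracting the mean over −500…−100 ms, and the amplitude time axis
is brought to 250 Hz (4 ms grid).

Numerical choices:

* **Kernel truncation** at ±5 σ_t. Shorter supports (±3.5 σ_t) leave
  spectral sidelobes that bias coefficients at the percent level on
  1/f-type signals (checked against an independent Morlet
  implementation in the test suite).
* **Two evaluation paths.** A full FFT convolution over the epoch, and
  a windowed direct evaluation at a selected set of output samples
  (classifier training/test points plus the baseline window). Both
  produce identical coefficients to single precision; the windowed path
  makes per-time-point decoding studies cheap. The path is selected
  automatically by the number of requested output times.
* **Rate conversion 480 → 250 Hz** by polyphase band-limited resampling
  (rational factor 25/48, edge-padded). Linear interpolation was
  rejected: its error for a band-limited component at frequency f is
  ≈ (2πf/480)²/8, i.e. ~7 % at 60 Hz, incompatible with preserving the
  upper half of the feature band. The resampling filter's edge
  transients stay inside the 1 s epoch margins.
* **Edge effects.** The 1 s margins absorb the wavelet support for all
  feature-band frequencies; an explicit error is raised when an epoch is
  shorter than the wavelet support at the lowest requested frequency.

Instantaneous theta phase (4, 5 and 6 Hz) is the argument of the same
Morlet coefficient, computed on the signal after a zero-phase (4th-order
Butterworth, forward–backward) 3 Hz high-pass, wrapped to (−π, π].
Phase is scale-invariant, so wavelet normalization is irrelevant there;
amplitude uses unit-energy normalization by default.

### 1.3 Decoding (`decode`)

At each training time point (−36 ms, then 44…764 ms in 80 ms steps; 11
points) features are the baseline-normalized amplitudes of all
(sensor, frequency) bins in 13–79 Hz. Feature selection keeps bins whose
paired two-tailed t statistic over the 20 indoor/outdoor pairs has
p < 0.05, independently per training time; an empty selection refuses
training. The classifier is a feedforward network — selected features →
20 logistic hidden units → 2 logistic outputs, targets (1 0) indoor /
(0 1) outdoor — trained by conjugate gradients (Polak–Ribière with
restarts) on the summed squared error, stopped after 20 iterations.
Features are z-scored with training-set statistics before entering the
network; weight initialization is small uniform from a per-classifier
seed.

Leave-one-out cross-validation re-runs feature selection inside every
fold on the training trials only. Folds are *balanced*: when a trial is
held out, its category partner is dropped from that fold's training set
(19+19 training trials). An unbalanced 19-vs-20 fold biases held-out
accuracy measurably below chance — enough to corrupt the chance-level
sanity check at the pre-stimulus baseline classifier — so the balanced
variant is the package's default. Held-out prediction uses the winning
output unit.

During maintenance each trained classifier is applied at 250 evenly
spaced test points spanning delay+250 ms … delay−250 ms (≈18 ms apart,
snapped to the 4 ms grid). A single-trial output is *correct* when the
unit matching the trial's true category exceeds 0.95; outputs exceeding
0.95 on both units are flagged as ambiguous and never counted correct.

### 1.4 Reactivation detection (`replay`)

If C of the n = 20 trials of one category are correct at a test point,
C is referred to a one-tailed binomial test against chance r = 0.5 using
the normal approximation (no continuity correction; an exact binomial
tail is the referee in the test suite). The per-comparison threshold is
Bonferroni-corrected over the 250 × 11 family: 0.05/2750 ≈ 1.8 × 10⁻⁵,
which only perfect 20/20 classification passes — by the exact and the
approximate route alike. (The approximation tracks the exact tail
within a factor of 3 through 19/20 and drifts to a factor ≈4 at 20/20;
the accept/reject decisions agree at every count.) Time points passing
the threshold are *reactivation times*; counts are totals of such time
points per subject, condition pair and classifier. For the coupling
stage, per-trial events from classifiers 44–764 ms are merged with
duplicate (trial, time) detections collapsed to one event. Count
contrasts between conditions are paired one-tailed t-tests on
per-subject totals.

### 1.5 Theta coupling (`coupling`)

For trial j with events at measured theta phases φ_nj,

PLV_j = |Σ_n exp(i φ_nj)| / N_j,   z_j = arcsin(2 PLV_j − 1).

Trials with fewer than 2 events are excluded (one event gives PLV = 1
trivially); the phase at an event is read from the 250 Hz phase store at
the nearest sample. For N uniform phases E[PLV] ≈ (√π/2)/√N — the
small-sample bias. **Caveat:** when two conditions are compared on
*detected* events, unequal event counts turn this bias into a spurious
PLV difference (the sparser condition looks more coupled everywhere).
The calibration studies therefore contrast conditions at matched planted
rates; interpretation of detected-event contrasts at unmatched counts
must account for the bias.

Condition contrasts are paired t-tests over subjects on the trial-mean z
per sensor (subject-level pairing is the default; the trial-level
alternative is a one-line change on the PLV table). Sensor multiplicity
is controlled by a cluster-based permutation test: sensors with
two-sided p < 0.05 are grouped under the layout adjacency (grid layouts:
all eight surrounding cells; irregular layouts: symmetrized 6-nearest
neighbours), candidate clusters need ≥ 8 members, and the cluster mass
(summed |t|) is compared with the maxima over within-subject
condition-label sign flips. With m subjects the attainable p-value floor
is 2/2^m; studies asserting small cluster p-values use enough subjects
or permutations to resolve it.

A within-subject permutation gives per-sensor significance of the phase
locking itself: each trial's event vector is circularly shifted by a
uniform random offset against its phase series, preserving the events'
temporal autocorrelation. Note the method's structural blind spot: for a
perfectly stationary oscillation a circular shift is a rigid phase
rotation and PLV is rotation-invariant, so locking to a noiseless
constant-frequency theta is undetectable by construction — real (and
synthetic) theta must wander for the null to have power.

Coupling–behavior association is the per-sensor Pearson correlation
between subject trial-mean z and behavioral accuracy, flagged at r > 0.7
and p < 0.05 (two-tailed), reported for flagged sets of ≥ 8 adjacent
sensors.

## 2. The synthetic cohort generator (`synth`)

Every epoch is a sum of

1. **1/f background noise** — white noise spectrally shaped to power
   ∝ f^(−1) (exponent configurable), unit variance per series;
2. **ongoing band activity** — 13–79 Hz band-passed noise of amplitude
   1.0 relative to the background, amplitude-modulated within trial on a
   ~300 ms timescale and scaled per trial by a lognormal gain
   (σ = 0.25);
3. **ongoing theta** (6 Hz, amplitude 2.0) — coherent within spatial
   sensor clusters (grid quadrants by default). The cluster designated
   as *coupled* for a condition keeps a fixed phase across trials (small
   jitter, σ = 0.2 rad); the other clusters get a random phase offset
   *and* a random frequency detune (±0.5 Hz) per trial, so their theta
   decoheres from the event train within a trial. A per-trial constant
   offset alone cannot lower a per-trial PLV (rotation invariance), so
   this detuning is what makes the coupling topography recoverable;
4. **category patterns** — each (category, condition) pair owns a
   distinct set of 4 carrier frequencies on the 33–79 Hz grid and a
   random sensor-weight map over ~40 % of sensors. Carriers are assigned
   by a stratified draw (one per frequency stratum per pattern, equal
   amplitudes) so that all six patterns are equally detectable — in-bin
   wavelet noise grows with frequency, and unbalanced draws would make
   detectability a per-condition lottery. This mirrors the
   counterbalancing of stimulus material across conditions in the study
   design being emulated. The pattern is on during the 3 s sample window
   (100 ms raised-cosine ramps) at amplitude `pattern_snr` (default 0.8)
   relative to the background;
5. **replay bursts** during maintenance — the same pattern re-injected
   for `burst_duration` = 150 ms (Hann envelope) at amplitude
   `pattern_snr × burst_gain` (default gain 3).

Replay events are drawn one per theta cycle with probability
λ/f_θ — so the mean rate is λ events/s and the construction caps λ at
f_θ — and each event is placed at the time where the trial's planted
theta attains a phase drawn from von Mises(μ, κ). The planted phase is
recorded in the ground truth: the generator's coupling parameters are
*exactly* the quantities the PLV stage estimates. Control trials never
contain replay events.

### 2.1 Reference conditions and why

* **Rates** λ = 5.7 (configural), 4.2 (nonconfigural), 0 (control)
  events/s at 6 Hz theta — replay in most theta cycles, the regime the
  theta-nested-replay model describes. The 20/20 detection rule is
  brutally conjunctive: a reactivation time needs *every* trial of a
  category simultaneously in a correctly-classified state, so detected
  counts scale roughly like (q·p_on + (1−q)·p_rest)^20 with q = λ/f_θ.
  High per-cycle probabilities are what make detection possible at all;
  the q-gap between conditions is what the count ordering recovers.
* **Sustained pattern vs bursts** (0.8 vs gain 3): with a strongly
  separable sustained pattern, pattern-free delay activity is a far
  extrapolation for the network and its arbitrary, near-constant output
  can exceed 0.95 for a whole category — producing whole-delay false
  reactivations. The weaker sustained pattern puts encoding LOOCV in
  the realistic 0.85–0.95 range and keeps the rest state inside the
  training cloud, while the stronger transient bursts keep
  p(correct | burst) high.
* **Within-trial band-power modulation**: without it, the per-trial
  gain alone leaves some trials on one side of the 0.95 threshold for
  the entire delay, and those trials complete false 20/20 coincidences;
  with it, rest-state correctness decorrelates across time points and
  trials and the control condition sits at the false-positive floor.
* **Coupling** κ = 8, μ = 0 by default (concentrated but not
  degenerate); per-condition coupled clusters (nonconfigural: cluster 0,
  configural: cluster 1) emulate condition-specific theta networks.
* **Behavior**: subject accuracies default to 0.83/0.97/0.79
  (control/nonconfigural/configural) with σ = 0.02 noise; a configurable
  linear slope on the subject's κ (with a per-subject κ spread) supports
  correlation-recovery studies. The slope is 0 by default.

All randomness derives from a single seed; per-sensor noise streams are
keyed by sensor identity, so permuting the layout permutes the output
identically. `generate_ground_truth` reproduces the full event/theta
bookkeeping without synthesizing signal, for statistical calibration
studies that only need planted phases.

### 2.2 What the generator does *not* emulate

No cortical source geometry or field spread (sensor patterns are
arbitrary weight maps), no eye-blink/cardiac artifacts, no evoked
broadband response shared by the two categories, no between-subject
anatomy: passing recovery tests shows the *statistics* behave as
designed under the stated signal model, not that the pipeline is robust
to every pathology of real recordings.

## 3. Validation studies and problem sizes

The studies in `thetareplay.studies` are shared verbatim by the analysis
drivers, the test suite and `scripts/acceptance.py`. Desk-scale sizes
were chosen as the smallest cohorts at which each question is
statistically meaningful:

* **Baseline chance level** — full 8-subject cohort, 64 sensors, all
  three conditions, LOOCV at −36 ms (960 held-out predictions). The
  grand mean must lie in the 95 % Monte-Carlo band around 0.5.
* **Coupling recovery** — one subject per κ ∈ {0, 1, 4, 20} at 16
  sensors, planted events read against the *measured* 6 Hz phase;
  trial-mean PLV must be monotone in κ and the preferred phase at
  κ = 20 recovered within ±0.2 rad.
* **Count ordering and specificity** — 8 subjects, 24 sensors, 4
  classifier training times, 100 maintenance test points, all 9
  (trained × tested) condition pairs. Counts scale with the number of
  classifiers and test points, but the ordering and specificity
  contrasts do not depend on them. Verified on independent cohort
  seeds during development.
* **Error control** — cluster-permutation family-wise error over 40
  null cohorts (equal rates, κ = 0; planted-phase path; 36-sensor grid,
  500 permutations), and the feature-selection type-I rate over 200
  null replicates of 64 × 38 bins.

## 4. Orchestration

`PipelineConfig` (YAML-serializable, schema-validated) carries every
stage's parameters with the reference constants as defaults; each stage
reads only the persisted artifacts of its predecessors (HDF5 chunked
arrays with JSON sidecars, tab-separated layouts, CSV tables), so the
chain is re-runnable from any checkpoint. The run report echoes the
config, its hash (output location excluded) and per-stage summaries,
wall times and artifact checksums; two runs of the same config and seed
produce byte-identical tables. The pipeline's default coupling contrast
is configural vs nonconfigural — with control planted event-free, the
classic memory-vs-control PLV contrast has no defined control-side PLVs
in the synthetic world.

## 5. Known limitations

* The 20/20 detection rule makes counts extremely steep in every
  per-trial probability; small cohorts show heavy-tailed counts, and the
  paired contrasts (not the raw counts) are the stable quantities.
* Detected-event PLV contrasts inherit the small-N PLV bias when event
  counts differ between conditions (see 1.5).
* The circular-shift null cannot detect locking to a perfectly
  stationary oscillation (see 1.5); this is a property of the method,
  reproduced faithfully.
* The conjugate-gradient implementation (scipy's Polak–Ribière with
  restarts) is not bit-identical to other CG variants with restart
  heuristics; all results tie to the package's own seeds.
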