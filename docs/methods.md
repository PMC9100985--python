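# Methods

## Problem and data model

The pipeline forecasts intraoperative hypotension from a single channel:
invasive arterial blood pressure sampled uniformly at 100 Hz (`Recording`).
Mean arterial pressure (MAP) is proxied throughout by the 2 s **trailing**
moving average of the waveform; hypotension is MAP proxy < 65 mmHg. The
trailing (causal) alignment is deliberate — a real-time system cannot see
future samples — and partial windows at the recording head are invalid
(NaN), never shortened. All durations become sample counts via
`round(duration · fs)`; spans are 0-based half-open.

A 2 s boxcar does not remove the pulse completely: at a 1.27 Hz heart rate
the fundamental is attenuated by |sinc(2 · 1.27)| ≈ 0.12, leaving ~±2 mmHg
of ripple on the MAP proxy for a 45 mmHg pulse pressure. Consequences drawn
consistently everywhere: episode ground truth is defined on the realized
moving average (below), and labeling-margin checks use episode plateaus a
few mmHg below threshold rather than exactly 65.

## Sample generation

Each candidate sample is three contiguous spans — observation 20 s, delay
300 s, class observation 60 s — advanced every 30 s (or 10 s). Labels use
strict whole-window conditions: hypotension iff the class window's MA
maximum is below 65 mmHg, normal iff its minimum is above; crossing windows
fit neither definition and are excluded (`ambiguous_class`) rather than
assigned an invented third class.

Exclusions, in precedence order: `partial_window` (MA undefined),
`artifact_obs`/`artifact_class` (artifact screen on the raw observation or
class window; the delay is not screened, as features and labels are not
read from it), `event_in_obs_or_delay`, `ambiguous_class`,
`duplicate_event`.

The event-exclusion rule needs care. A hypotension sample's class window is
entirely below threshold, so the threshold crossing of the very event being
forecast always falls in the delay tail of its own sample; excluding on any
instantaneous sub-threshold MA in the delay would therefore exclude every
positive and the class could never occur. The implemented rule is:

* any sub-threshold MA inside the **observation** excludes (the event has
  visibly reached the feature window), and
* a contiguous sub-threshold stretch of at least one class-observation
  length (60 s) inside **observation+delay** excludes (hypotension is
  already ongoing, prediction is pointless).

Under this rule the windows surviving for a given episode are exactly those
targeting its first sub-65 minute; with a 30 s stride up to two such windows
exist, and `duplicate_event` suppression (one hypotension sample per maximal
sub-threshold MA run) keeps only the first — a single alarm per event.
`event_in_span` also exposes the instantaneous mode (`min_event_samples=1`)
for direct dip queries.

## Feature families (36 values)

Computed on the raw (unsmoothed) observation window; smoothing is used for
labeling only.

* **Statistics (9)** — mean, max, min, sample sd (ddof = 1), skewness (third
  standardized moment; 0 for constant windows), excess kurtosis (−3 offset;
  near-sinusoidal pulses give ≈ −1.5, matching the negative values seen in
  clinical tables), RMS, RSS, IQR (linear-interpolation quartiles). RSS
  defaults to the textbook `sqrt(Σx²)`; a `rms_times_n` convention switch
  exists because some clinical feature tables print RSS ≈ RMS·n.
* **Peaks (8)** — "peaks" are downward excursions: local minima with
  prominence ≥ 1 mmHg and spacing ≥ 0.3 s, kept when below 65 mmHg. Count,
  mean/sd of inter-trough intervals (in samples at native rate — one heart
  period ≈ 80 samples), mean/max/min/sd of trough values, and the crest
  factor max(window)/RMS(window) over all samples (the convention pinned by
  the clinical table's max/RMS ≈ printed crest factor). Windows with no
  troughs report 0 sentinels; tree ensembles tolerate them.
* **Change (3)** — binary indicators of one changepoint in mean, variance,
  mean+variance. Exhaustive single-split search (both segments ≥ 8 samples)
  over Gaussian segment costs `n·log(variance)` — mean: SSE about segment
  means, shared variance; variance: deviations about the global mean;
  mean+variance: both free — accepted when the cost drop beats a BIC
  penalty `p·log(n)` with p = 2/2/3 freed parameters. Capped at one change
  per statistic, so indicators are {0, 1}. A variance floor of
  `max(var, 1)·1e-10` keeps near-constant segments finite and makes the
  constant window yield all zeros.
* **Fourier (6)** — one-sided periodogram of the mean-removed window, DC
  excluded (otherwise DC would always win and the heart-rate line could
  never rank first); top three ordinates and their frequencies, ties broken
  toward lower frequency; adjacent bins may all qualify, as for any strong
  pulse line. Bin width at 20 s is 0.05 Hz.
* **Wavelet (10)** — Morlet continuous wavelet transform over a fixed
  96-point logarithmic scale grid whose pseudo-periods span 0.1–10 s
  (scale = period · f_c · fs with the Morlet center frequency f_c ≈ 0.8125,
  so a pure sinusoid of period T scores scale1 = T within one grid step,
  ratio ≈ 1.05); per-scale energy is Σ_t |coefficient|²; features are the
  pseudo-periods of the ten highest-energy scales, by descending energy.
  For a 1.27 Hz pulse, scale1 ≈ 0.79 s ≈ 1/freq1.

Feature order is fixed and public (`FEATURE_NAMES`); family sizes are
9 statistics, 11 peak-and-change, 6 Fourier, 10 wavelet.

## Classifier protocol

100-tree random forest, Gini criterion, bootstrap bagging and random
feature subsets (scikit-learn defaults for depth and subset size),
deterministic given a seed. Class imbalance is treated by duplicating
minority rows with replacement until classes are equal — **strictly inside
each training fold**; held-out folds keep their natural imbalance.
Stratified 5-fold cross-validation is per-sample by default, mirroring the
original protocol; `group_by_patient=True` keeps each patient's windows on
one side of every fold. Metrics: accuracy over both classes,
precision/recall of the hypotension class (precision with no positive
predictions reported as 0 with a `precision_defined=False` flag so weight
sweeps complete), per-fold ROC curves with trapezoid areas, and
mean-decrease-in-Gini importances normalized to sum 1. Explicit class
weights `"a:b"` put weight a on the hypotension class and b on normal, so
the sweep none → 6:4 → … → 9:1 shifts cost toward missed events and recall
rises monotonically while precision is compromised.

## The simulator and what passing tests show

`synthetic_ibp` generates the study data: per beat, a fixed analytic
morphology (dominant systolic bump at phase 0.22 of width 0.11, dicrotic
bump at 0.55), zero-mean, normalized to unit peak-to-trough, scaled by the
45 mmHg pulse pressure; widths chosen so the fundamental dominates the
spectrum and spectral features recover the heart rate. MAP is baseline plus
an Ornstein–Uhlenbeck drift (stationary sd 2 mmHg, relaxation 60 s).
Episodes are trapezoids (ramp/plateau/recovery) to a plateau MAP;
artifacts (240 mmHg spikes, 5 mmHg drops, flatlines) overwrite the clean
signal. Defaults: MAP 85 mmHg, heart rate 1.27 Hz, consistent with the
clinical vital-sign table. All randomness flows from one integer seed;
identical config ⇒ bit-identical output.

Ground-truth hypotension annotations are the maximal runs where the 2 s
trailing MA of the *generated* waveform is below 65 mmHg (runs within one MA
width of each other merged; runs touching artifacts attributed to the
artifact). Defining truth on the realized MA rather than the noiseless
trapezoid makes labeling-recovery checks exact: the trailing MA lags the
underlying MAP at episode edges, so trapezoid-based intervals would be
systematically offset.

Two study generators exist. `default_study_config` is naturalistic:
baselines U(75, 95) mmHg, heart rates U(0.9, 1.6) Hz, Poisson-placed
episodes (2/h) and artifacts (3/h). `learnable_study_config` is the
controlled experiment: baselines U(82, 92) mmHg, at most two episodes per
30 min patient, each optionally preceded by a raised-cosine MAP dip
(default 12 mmHg deep, 120 s wide, centered 290 s before the episode's
nominal 65 mmHg crossing — exactly where the surviving sample's observation
window falls given the 20 s + 300 s geometry and 30 s stride). Its episodes
keep a 420 s pre-onset clearance and recover in 8–15 s (promptly treated
hypotension): without these, pre-episode observation windows can overlap an
earlier episode's tail, and slow recoveries feed low-MAP windows into the
normal class — both genuine signals that would contaminate the no-precursor
negative control. With the dip set to zero the pre-episode waveform carries
no information about upcoming events, and grouped cross-validation scores
chance AUC; per-sample CV on the same data sits slightly *below* chance — a
prevalence-depletion artifact of patient-clustered rows (a held-out
positive depletes its own patient's training prevalence), which is why the
negative control uses the grouped protocol.

What passing tests do **not** show about real data: the simulator has no
beat-to-beat variability, respiratory modulation, baroreflex dynamics or
treatment responses; its precursor is injected by construction, whereas
real pre-hypotensive signatures are weaker and heterogeneous (clinically
reported recall at 5 min is ≈ 0.5, not 0.9). The tests validate the
*pipeline* — windowing, exclusions, features, protocol — not clinical
effect sizes.

## Numerical choices and degenerate inputs

Moving average via cumulative sums (float64 exact at mmHg scale); empty or
too-short inputs raise. Constant windows: sd/skewness/kurtosis/IQR all 0,
periodogram powers 0 with the three lowest non-DC bins reported, wavelet
energies 0 with grid-order scales, no changepoints. Single-trough windows:
interval statistics 0. Ties in periodogram power break toward lower
frequency; wavelet energy sorting is stable on the fixed grid.

## Problem sizes

The bundled studies are scaled for a laptop: 20–50 patients × 30 min
(~1,700 candidate windows per 50 patients at a 30 s stride) versus 888
patients in the clinical study; feature extraction runs at ~50 ms per
window, dominated by the 96-scale CWT. Fractions of hypotension samples in
simulated studies (~2–5%) match the clinical imbalance (4.7% / 1.3%).

## Known limitations

* Batch processing only; no streaming emission.
* Single channel (IBP); no ECG/PPG/capnography fusion.
* The changepoint search is single-split by design (indicators, not
  segmentations).
* Per-sample CV reproduces the original protocol but is subject to the
  patient-coupling bias described above; grouped CV is provided and
  preferred for scientific claims.
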