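# Methods

## Problem and model

The package predicts whether a one-minute single-lead ECG segment
precedes an imminent episode of sustained ventricular tachycardia or
fibrillation. The underlying physiological signal is that in the tens
of minutes before onset, beat timing and QRS morphology drift: RR
intervals shorten, QRS complexes widen, and Q/S amplitudes change,
while the rhythm still looks superficially normal. The method makes no
attempt to model the arrhythmia itself; it classifies pre-onset
"apparently normal" minutes against minutes from subjects with no
arrhythmia, using only time-domain quantities that can be computed in
real time.

The classifier is a binary CART decision tree. A segment's feature
vector holds, in canonical order: mRR, mHR, SDNN, RMSSD (beat-timing
statistics in s and beats/min), mQRSd, sdQRSd (QRS duration statistics
in s), and mQamp, sdQamp, mRamp, sdRamp, mSamp, sdSamp (Q/R/S
amplitudes in mV).

## Preprocessing

Records are truncated to 35 minutes so both source classes have a
common length. Impulsive artefacts are replaced with a Hampel-style
rule: a sample deviating from its 1-second sliding median by more than
3 scaled MADs (x1.4826) is replaced by the nearest preceding clean
value. The source material names the replacement rule ("previous
value") but not the detection criterion, so the median/MAD detector is
this package's own choice; `window_s` and `n_mad` are exposed. The
pass is iterated to a fixed point (usually 2–3 iterations) so the
operation is idempotent. Constant windows (MAD = 0) declare no
outliers, which keeps flat-line and pacing-spike-free signals
untouched.

Segmentation uses half-open windows [start, start + 60·fs) with
0-based indexing. For a pre-arrhythmic record, the segment containing
the annotated onset and everything after it are excluded.
Minutes-before-onset is measured from the *segment end*, because a
prediction would be issued when the minute completes.

## QRS detection

The detector is the classic Pan-Tompkins chain with canonical
parameters: band-pass 5–15 Hz (2nd-order Butterworth, applied
zero-phase so fiducial indices are not lag-shifted), five-point
derivative, squaring, 150 ms moving-window integration, adaptive
signal/noise levels with update fraction 0.125, 200 ms refractory, and
search-back at 1.66x the running RR average with a halved threshold.
The first 2 s initialise the thresholds (peaks there are still
reported when confident). Reported indices are refined to the local
band-passed maximum within ±150 ms. All thresholds are relative, so
detection is invariant to amplitude scaling.

## Fiducial points and validation

Q and S are the minima of 100 ms backward/forward windows around each
R-peak, clipped at neighbouring peaks. Q-onset and S-offset are found
by scanning outward from Q/S for the first sample whose centred slope
magnitude falls below 2.5% of the beat's maximal absolute slope
(`slope_eps = 0.025`), bounded by 80 ms; when no such sample exists the
bound is returned and the beat flagged. "Nearly zero slope" has no
published quantification, so the 2.5% fraction is a package choice,
exposed in configuration. Validators mark beats invalid when fiducials
are mis-ordered (qon ≤ q < r < s ≤ soff must hold) or when QRSd falls
outside 40–200 ms; invalid beats are excluded from all morphology
features. RR statistics use all detected R-peaks.

## Feature conventions

Two formulations in the source material are ambiguous and both options
are implemented:

* **Heart rate.** As printed, the HR formula divides 60 by the *total*
  RR time, which is not in beats/min when RR is in seconds. The
  default is mHR = 60/mean(RR), the standard definition, which also
  guarantees mRR·mHR = 60 exactly; the per-interval mean of 60/RRi is
  available via `hr_method="inst"`.
* **Denominators.** The printed statistics normalise by "total number
  of beats" n although the sums run over m = n−1 intervals (or m−1
  successive differences). Default: divide by the number of summed
  terms; `denominator="beats"` reproduces the literal text.

Amplitudes are measured on the raw (de-outliered) signal — band-pass
filtering distorts amplitude — relative to a per-beat isoelectric
baseline taken as the signal value at Q-onset, since no baseline
convention is published. SDNN and all sd* features are
population-style (divide by the number of terms).

## Feature selection

A CART is grown on all 12 features (Gini impurity by default; an
MSE-on-labels impurity is available and yields identical splits for
0/1 labels, with risks halved). Predictor importance is
Imp(f) = Σ over branch nodes splitting on f of (parent risk − child
risks) divided by the total number of branch nodes; features never
split on get exactly 0. Split ties are broken deterministically by
lowest feature index, then lowest threshold, so a duplicated feature
appearing later in canonical order can never absorb importance. No
pruning; nodes stop at purity or below 10 samples (`min_split`).

The incremental profile fits the top-k ranked features for k = 1..12
under stratified 10-fold CV repeated with seeds 1–5 (partition: seeded
per-class shuffle, then round-robin assignment). MSE on 0/1 labels is
the pooled test-fold misclassification rate. The optimal size is the
smallest k whose mean MSE lies within one SD (the SD at the minimising
k) of the global minimum; when per-k SE/exT measurements are supplied,
candidates tied on SE prefer the smaller k. This formalises the
published argument for choosing 8 of 12 features, and applied to the
published MSE table it selects exactly 8.

## Classification and evaluation

Positives are binned into five 5-minute intervals before onset —
interval r covers ((r−1)·5, r·5] minutes — and matched 1:1 with
normal-record segments at the same minute position (the matching rule
is a package choice; the source is silent). Three classifiers are
compared on the selected subset: the CART above, Gaussian naive Bayes
(variance floor 1e−9), and a linear soft-margin SVM (C = 1, no
standardisation by default). Score ties predict class 0 (normal),
favouring specificity. Evaluation is stratified 5-fold CV repeated
with seeds 1–5, pooling test-fold confusions per seed.

SE = 100·TP/(TP+FN), SP = 100·TN/(TN+FP). Report tables append an
Average row (simple mean over the five interval values — this
convention reproduces the published averages) and an SD row using the
*sample* standard deviation: the published Average/SD rows are
reproduced exactly by n−1 normalisation (e.g. SE values 86.67, 88.89,
82.50, 95.00, 93.33 → 89.28 ± 5.05), not by the population formula.

Execution time is the median wall-clock duration of one prediction
call after a warm-up. It is hardware-bound: only ordinal statements
(fewer features not slower) are meaningful, and exT columns are the
one part of the reports that is not bit-reproducible across runs.

## Synthetic data

`synth_ecg_record` builds beats as sums of Gaussian bumps (P width
~40 ms, amplitude 0.12 mV; T width ~120 ms, 0.30 mV; Q/R/S widths tied
to the requested QRS duration, with Q/S centred at ±0.32·QRSd around
R). RR intervals are mean_rr plus Gaussian jitter truncated at ±3 SD.
A pre-arrhythmic record ramps mean RR down (−15% at onset) and QRS
width up (+20%) linearly toward the annotated onset, then switches to
a coarse 5 Hz fibrillation-like oscillation. Exact per-beat ground
truth (R, Q, S, onset/offset samples) is emitted alongside.

The study-shaped corpus is 9 normal records at 128 Hz plus 9
pre-onset records at 250 Hz, 35 minutes each, onset at minute 30, with
per-record physiology (mean RR 0.7–1.0 s, jitter 20–50 ms, QRS
80–100 ms, amplitudes varied) drawn from sub-seeded distributions so
classes are not separable by any single constant. `synth_dataset`
bypasses the signal level: class-conditional unit-variance Gaussians
with stated per-feature mean shifts, positives tagged uniformly over
(0, 25] minutes.

What the generator does *not* emulate: baseline wander, electrode
motion artefacts, ectopic beats, T-wave morphology changes, or real
pre-VT/VF dynamics. Tests passing on synthetic data therefore
demonstrate the pipeline's internal correctness and parameter
recovery, not clinical performance; replication on the published
per-segment dataset (placed at `data/s1_dataset.csv`) is the test of
the latter.

## Numerical choices and problem sizes

* Derivative and integration kernels use edge-replicated padding so a
  constant signal yields an exactly zero envelope.
* Duration features at 128 Hz carry ±1 sample (7.8 ms) quantisation
  per delineated edge; cross-rate comparisons of mQRSd use an absolute
  two-sample tolerance while rate-robust features agree within 5%.
* Fold partitions that would leave a training split single-class are
  redrawn with an incremented sub-seed (logged); interval datasets with
  fewer positives than folds reduce the fold count.
* Default experiment sizes: 18 records x 35 min for the corpus run;
  20 x 60 s records for detector recovery; 300 per class for the null
  calibration. These are the package's standard experiment scales and
  complete in a few minutes on one core.

## Known limitations

* Single-lead, upright-R morphology assumed; the detector refines to
  the band-passed *maximum* and would need inversion handling for
  leads with negative R deflections.
* Onset annotations are taken as given; no rhythm detector is
  implemented, so records without annotations cannot contribute
  positives.
* The WFDB-dialect reader supports format 16 single-signal files and
  the onset subset of MIT annotation codes — enough for round-tripping
  this package's own output and standard format-16 exports, not a
  general WFDB implementation.
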