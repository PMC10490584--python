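# Methods

This note documents the models, parameter choices and numerical decisions
behind the two pipelines, the scoring rules, and the synthetic-data
generator, including what the generator does and does not emulate.

## Signal model and assumptions

Both pipelines assume two uniformly sampled channels at a common rate
(250 Hz is the working default): a single-lead ECG with a conventional
PQRST morphology, and a thoracic respiration trace whose dominant energy
lies in the breathing band (0.15–0.5 Hz) with small cardiac-synchronous
ripples ("cardiogenic oscillations") superimposed. Three physiological
couplings link the channels: respiratory sinus arrhythmia modulates the
R–R interval, electrode–heart geometry modulates the R amplitude, and
thoracic impedance changes modulate the Q-trough depth. The mechanical
appearance of a heartbeat in the chest signal lags electrical systole by
roughly 120 ms; detection subtracts this constant.

All filters are zero-phase (forward–backward 4th-order Butterworth), a
deliberate choice: every downstream decision compares event times against
windows of ±140 ms, so group delay must be eliminated rather than merely
compensated. The band edges themselves (1–9 Hz cardiac isolation, 0.2–0.5
and 0.15–0.5 Hz breathing, 0.5–5 Hz post-squaring, 1–25 and 0.1–25 Hz ECG
conditioning) are fixed by the procedure; the filter family and order are
implementation choices and remain config-overridable.

## RDC: heartbeats from respiration

1. **Interval estimation.** Breaths are peaks of the 0.2–0.5 Hz band-passed
   trace with a minimum spacing of 2 s and a prominence of 10% of the
   filtered maximum (the breath detector's thresholds are our choice; they
   are far from critical because only the *mean* breath interval is used).
   Expected inter-beat interval = mean breath interval / beats-per-breath.
   The ratio defaults to 3 and is configurable; in real populations it
   spans roughly 1.8–4, which is the single largest error source of the
   method. Adaptive per-record updating of the ratio is deliberately out of
   scope. Estimates outside 0.3–2.0 s trigger a warning.
2. **Cardiac extraction.** Band-pass 1–9 Hz; subtract a 3rd-order
   Savitzky–Golay baseline whose frame is the expected inter-beat interval
   in samples (rounded up to odd); subtract a 30 ms moving mean — long
   enough to span a T-wave-scale bump, shorter than the inter-beat gap —
   then add the mean absolute value, square (fixed gain 1; any positive
   gain is equivalent because all detection thresholds are relative),
   band-pass 0.5–5 Hz and clip negatives.
3. **Detection.** Peaks at least 65% of the expected inter-beat interval
   apart and above 8% of the processed-trace *mean* (the "average height"
   is interpreted as the signal mean, not the mean of candidate peak
   heights; both readings are defensible and the choice is exposed in
   config), minus the 120 ms delay.

A result is flagged low-confidence when the detected count falls outside
0.5–2× the count implied by the interval estimate, or when the coefficient
of variation of the detected inter-beat intervals exceeds 0.15 — genuine
sinus rhythm under respiratory modulation stays well below this, while
noise-driven detections scatter between the refractory floor and the next
chance peak (empirically CV ≈ 0.2 on breathing-plus-noise records with no
cardiac content).

## EDR: respiration from ECG

R anchors come from the 1–25 Hz band-passed, squared, twice 75-sample
moving-mean-smoothed trace (peaks ≥160 samples apart, prominence ≥0.5% of
max). The R–R series is anchored at the midpoint of each peak pair — a
symmetric choice; the value is the interval in seconds. Q troughs come from
the 0.1–25 Hz trace rectified to its negative half, inverted, smoothed
three times (frame 75), with peaks above 10% of max and ≥160 samples apart.

Cleaning removes points whose |value| exceeds 300% of the series' mean
|value|; the threshold mean is computed once, before any removal (a single
pass, not iterated). Survivors are divided by their mean |value| so each
series is unitless with mean |value| exactly 1 — this is what makes an
amplitude in volts, an interval in seconds and a trough depth commensurate.
Raw-trace despiking (reference respiration) replaces samples more than
8 MAD from the median with the previous retained sample.

The three series are cubic-spline interpolated onto the uniform grid over
the overlap of their spans (≥10 s required), averaged (division by 3 —
"averaging" is read as the arithmetic mean; the subsequent 300-sample
moving mean is a separate smoothing step, and the choice is config-exposed),
smoothed, and band-passed to 0.15–0.5 Hz. Composite inspiration maxima use
the same detector settings as the reference respiration (prominence 2.5% of
max, spacing ≥250 samples).

Phase alignment searches shifts 0, 0.2, …, 1.4 s *subtracted* from the
composite peak times, minimizing the mean absolute nearest-reference-peak
distance (the alignment objective is our formalization; only "average
difference to reference peaks" is prescribed). Scoring then labels each
shifted peak TP within 0.5 heartbeats of an unmatched reference,
"inaccurate" within 0.5–1 heartbeat, else FP; the heartbeat period is the
record's own mean R–R interval.

## Scoring and metrics

Beat classification uses greedy nearest-first matching: all
detected-reference pairs within ±140 ms are taken in order of increasing
distance (exact ties: earlier reference, then earlier detection), each
reference consumable once. Unmatched detections 140–320 ms *after* a
reference are tallied as T-wave hits, separate from plain false positives;
precision is TP/(TP+FP). The matching discipline is a design choice — the
window rules alone do not fix it — and greedy nearest-first is not always
cardinality-maximal; it is, however, deterministic, order-independent, and
matches clinical beat-scoring practice.

Windows for rate comparison are half-open [w, w+60) s stepped by 10 s;
rate = count × 60/window. NRMSE divides the RMSE by the reference range
and is reported absent for a constant reference. Pearson's coefficient is
the standard product-moment form with the two-sided n−2 d.f. t-test
p-value; an alternative "printed" variant with a difference instead of a
product under the denominator's absolute value is available for audit but
does not reproduce the product-moment coefficient. Concordance uses
population (1/n) second moments, so calc = ref gives exactly 1 and any
additive bias strictly lowers ρ_c below ρ_p.

Waveform correlation: per non-overlapping 32 s section, the maximum
normalized cross-correlation over lags within ±3 s, averaged over sections.
Window means and variances are computed per lag (sliding sums), and among
near-equal maxima the smallest |lag| wins — relevant for quasi-periodic
waveforms where a lag of ±one breathing period ties the true lag. Note the
best-lag maximum inflates the null: independent band-limited noise scores
≈0.4, not 0, because each 32 s section has only ~20 effective degrees of
freedom and several effective lags; coherent waveforms score >0.95.

## Synthetic records

The generator emulates exactly the couplings the pipelines exploit: beat
times from an integrate-to-threshold process with rate
hr·(1 − rsa·sin φ)/60 (φ = breathing phase; the sign makes the R–R
*interval* rise with inspiration, in phase with the amplitude
modulations — "coherent" coupling); ECG as a train of five-Gaussian PQRST
templates with R amplitude ×(1 + 0.15 sin φ) and Q depth ×(1 + 0.15 sin φ);
respiration as a unit breathing sinusoid plus 0.1-amplitude baseline wander
at 0.05 Hz, a Gaussian cardiogenic pulse (amplitude 0.05, σ 40 ms) placed
120 ms after each beat, 50 Hz powerline hum (amplitude 0.02) and white
noise (SD 0.01 — cardiogenic amplitude five times the noise RMS). Defaults:
250 Hz, HR 60 bpm, RR 15 breaths/min — i.e. four beats per breath, against
the detector's assumed three, so the interval estimate is deliberately
imperfect in the default condition. One seed determines everything; a
noise sweep scales a fixed unit-noise realization so truth is shared
across levels.

What the generator does **not** emulate — and therefore what passing tests
do not demonstrate about real data: morphology variation between and
within subjects, ectopy and arrhythmia, motion artifacts, electrode noise
with heavy tails, breath-to-breath irregularity, amplitude drift, and
beats-per-breath ratios drifting over a recording. Recovery rates on real
recordings are substantially lower than on these records; the synthetic
suite verifies that the implementation is faithful and self-consistent,
not that the method solves the clinical problem.

## Numerical choices and degenerate inputs

* Moving means use windows clipped to the signal bounds (a constant maps to
  itself; no boundary transients); Savitzky–Golay and band-pass filters use
  mirror/odd reflection padding. Band-pass padding scales with the low
  cutoff (≈3/f_lo seconds), without which boundary transients dominate
  0.1–0.15 Hz bands on records of a few minutes.
* Even Savitzky–Golay frames are rounded up to odd with a warning (frame
  lengths derive from inter-beat intervals and need not come out odd).
* Peak search keeps, among candidates closer than the minimum distance, the
  taller; exact height ties keep the earlier index. An all-flat signal
  yields an empty peak set, not an error.
* Sample i of a signal lives at time t0 + i/fs (0-based); all scoring
  windows are closed intervals in seconds; window boundaries in rate
  computation are half-open so no event is counted twice.
* Problem sizes in the test and acceptance suites — ten 5-minute records,
  1000 metric-oracle pairs, 500 classification-oracle pairs — were chosen
  as the smallest sizes at which the binomial/sampling noise of the
  measured rates is comfortably below the asserted margins.

## Known limitations

The beats-per-breath ratio is fixed per run; records whose true ratio is
far from the assumed value get a mis-scaled Savitzky–Golay frame and peak
spacing floor, degrading sensitivity (low heart rates are the worst case).
The 120 ms delay is a population constant, not estimated per record. The
EDR phase alignment searches one global shift; slowly drifting phase is not
tracked. WFDB support covers single-.dat records in formats 16 and 212.
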