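# Methods

`pulsecal` implements a cuff-less hypertension screening pipeline: from
simultaneous ECG, photoplethysmogram (PPG) and arterial blood pressure (ABP)
recordings it derives pulse-propagation and waveform-morphology features,
classifies segments as normotensive (NTS) or hypertensive (HTS) at a
130 mmHg systolic threshold, and quantifies how much per-subject calibration
— prior labelled measurements of the test subject in the training set —
improves classification of new subjects. Because suitable ICU waveform data
cannot be shipped with a package, every stage is driven and validated by a
synthetic cohort generator whose ground truth is known exactly.

## The synthetic cohort

A cohort consists of `n_subjects` subjects, each with a stable NTS or HTS
label (class composition is exact: `round(prevalence * n)` HTS subjects,
order shuffled by the seed; the default prevalence 24/69 mirrors the target
study population). Each subject contributes `segments_per_subject` segments
of 120 s at 125 Hz, placed at configurable timestamps (default 0, 0.5 h,
3 h, 12 h, 48 h, 49 h so all four calibration-distance buckets are
populated).

Waveforms are sums of closed-form components, so first and second
derivatives — and therefore all fiducial ground truth — are analytic:

* **PPG pulse** = systolic Gaussian (width σₛ ≈ 63 ms) + dicrotic Gaussian
  (σ = 85 ms, delayed ~260 ms) + a windkessel-style exponential run-off with
  a smooth logistic onset. The run-off's time constant tracks the beat
  period (τ = RR − 0.3 s, clipped to [0.3, 0.9] s) so the diastolic decay
  still has slope when the next upstroke begins; this keeps the pulse onset
  a well-localized minimum at any heart rate. Each beat is shifted (two
  fixed-point iterations against the continuous model) so its waveform
  minimum lands exactly at the intended foot time.
* **ECG beat** = P, R, S and T Gaussian deflections. **ABP pulse** =
  two-Gaussian shape normalized so its maximum equals the requested per-beat
  SBP, riding on the diastolic pressure.

Physiology is encoded as couplings:

* **PAT–SBP**: the pulse foot follows the R peak by
  `PAT = 0.40 s − 0.001 s/mmHg × SBP` plus a per-subject offset
  (sd 0.03 s), a slow drift (0.005 s per hour times a signed subject factor
  with magnitude ≥ 0.7, so every subject's timing wanders over hours), a
  weak within-segment random walk, and per-beat jitter (sd 20 ms at the
  default noise level). PAT is clamped to [0.20, 0.33] s.
* **APG–SBP**: the dicrotic amplitude fraction is
  `0.30 + 0.001/mmHg × (SBP − 130)` plus a per-subject offset (sd 0.09)
  and a within-segment walk, so the second-derivative wave ratios carry
  pressure information but are confounded across subjects.
* **SBP**: subject baselines are drawn per class (NTS 112, HTS 152 mmHg,
  between-subject sd 6 mmHg) and truncated away from the 130 mmHg boundary,
  with segment-level wobble (`sbp_sd_within`, default 3 mmHg) and per-beat
  jitter also kept on the label's side — labels are stable by construction,
  matching a curated stable-label cohort.

`noise_sd` (default 0.005 relative) scales **both** additive sample noise
and all beat-level stochastic terms (RR, SBP and PAT jitter, the
within-segment walks). Setting it to zero therefore yields a fully
deterministic record in which PAT is exactly linear in SBP — the
configuration the recovery tests use. A 60 Hz mains component
(`powerline_amp`) is added to ECG and PPG.

Each subject also carries a *beat-noise scale* (lognormal, sd 1.0, clipped
to [0.3, 6]) multiplying the per-beat jitter of timing and morphology:
subjects differ in short-term physiologic variability.

Why these numbers: the simulator is calibrated to a *regime*, not to any
measured waveform — between-subject idiosyncrasy (timing offsets, morphology
differences, drift) dominates the SBP couplings, so a classifier trained on
other subjects transfers near chance, while any same-subject measurement is
highly informative. Per-beat jitter is large enough that a 10 s sub-segment
aggregate (~9 beats) is a noisy estimate while a full 120 s segment
aggregate (~110 beats) is stable; the heterogeneous beat-noise scale means
"difficult" subjects need several calibration measurements before a
same-subject nearest-neighbor match becomes reliable. Together these make
close-in-time accuracy rise gradually with the number of calibration
sub-segments instead of saturating at the first, while distant calibration
at segment granularity degrades only through the hour-scale drift.

What the generator does **not** emulate: arrhythmia, respiration modulation,
sensor-specific artifacts, measurement dropouts. Passing tests therefore
demonstrate correctness of the pipeline's algorithms and the calibration
logic under a plausible dependence structure — not clinical performance on
real ICU data, whose headline numbers are not reproducible without the
original recordings.

## Preprocessing

PPG: Chebyshev type-II band-pass, 0.5–10 Hz, 20 dB stop band, then mean
removal. "Fourth order" is interpreted as the order parameter of the
classic band-pass design routine (4 poles per band edge, an 8th-order
filter): the literal 4-pole band-pass has such soft edges that it attenuates
the ~0.9 Hz pulse fundamental to 0.57 and the 5 Hz harmonic to 0.73,
visibly deforming pulse feet. All filters are applied forward–backward
(zero phase); group delay would otherwise bias every timing feature, and
timing is the core signal here. ECG: 4th-order Butterworth high-pass at
0.5 Hz and low-pass at 50 Hz (the 60 Hz mains falls in the stop band; no
extra notch). Derivatives (VPG, APG) are central differences scaled to
physical units; the APG is smoothed by a centered 5-sample moving average
before extremum search — a second difference is otherwise noise-dominated,
and a symmetric kernel adds no timing bias.

An automated quality gate replaces visual triage: a record fails when the
ABP excursion is below 10 mmHg, when ECG- and PPG-derived beat rates
disagree by more than 20%, or when more than 1% of samples are non-finite
or rail-clipped (runs of ≥5 identical extreme values).

## Fiducial detection

R peaks: phasor transform φ[n] = arctan(x[n]/Rv) of a QRS-band (5–18 Hz,
zero-phase) enhanced ECG, with Rv = 0.25·max|x|. Candidate peaks of φ
separated by a 250 ms refractory period are accepted above an adaptive
threshold (60% of the running median of the last 8 accepted peak phases)
and refined to the ECG maximum within ±60 ms. The band-pass enhancement and
the moderate Rv are essential: with a very small Rv the arctan saturates
T waves and broadband noise to ±π/2 exactly as it does the QRS, and no
phase threshold can separate them.

Per R–R interval: S = PPG maximum in (R, R + 0.6·median RR] (capped at the
next R); O = PPG minimum in (R, S); W = VPG maximum and a = APG maximum in
(O, S]; b–e = the first alternating min/max/min/max of the APG after a,
within 0.75 s. A beat missing any landmark is dropped and counted with a
reason (complete-case per beat). Per-beat SBP is the ABP maximum within the
beat; a segment's label is NTS iff the mean beat SBP is below 130 mmHg
(the boundary itself goes to HTS, the alarm-safe side).

## Features

23 per-beat features (median-aggregated per segment or per 10 s
sub-segment; at least 3 usable beats or the unit is rejected): three pulse
arrival times (R→O, R→W, R→S), the ABP-peak-to-S transit interval (PTT —
optional, since it needs the pressure channel), systolic amplitudes of PPG
and VPG, peak-to-peak and onset-to-onset intervals (TPP, TPI), rising time,
half-height width, the areas before/after the systolic peak and their ratio
(IPA = A2/A1), total pulse area, the a–a interval, the signed APG ratios
b/a, c/a, d/a, e/a and the composites (b−c−d−e)/a, (b−e)/a, (b−c−d)/a,
(c+d−b)/a. Amplitudes, widths and areas are measured relative to the PPG
value at the beat's onset — the mean-removed signal has no per-beat zero,
and the onset value is the natural baseline. Inter-beat features use the
current and next physiologically consecutive beat and are undefined on the
last beat of a run.

## Selection, models, evaluation

Features are z-scored with training-set statistics (sample sd; zero-variance
columns dropped with a warning). Binary ReliefF (k = 10 by default,
Manhattan distance on range-scaled features, all instances, deterministic
tie-break by instance order) ranks features; a Pearson correlation matrix
flags redundancy. The default selection policy removes a fixed six —
(b−c−d−e)/a, (b−e)/a, (c+d−b)/a (near-collinear with the simple ratios)
and TPP, TPI, pulse area (lowest-ranked) — keeping 17 of 23; a data-driven
policy (|r| ≥ 0.95 pairs, then 3 lowest-ranked) is available.

Classifiers: KNN (k = 1, Euclidean; voting ties resolve toward NTS, the
non-alarm class), RBF-SVM (C = 1, bandwidth from the median pairwise
distance), and a bagged ensemble of 30 decision trees. HTS is the positive
class. Metrics: Acc = (TP+TN)/total, Se = TP/(TP+FN), Sp = TN/(TN+FP),
F1 = 2TP/(2TP+FP+FN). The count form of F1 is used because it is the one
consistent with published Acc/Se/Sp/F1 rows; `implied_f1` inverts
(Acc, Se, Sp) into prevalence, precision and F1 for exactly that
consistency check. The main evaluation is leave-one-segment-out with the
subject's other segments *in* training (the calibrated regime);
normalization is refit inside each fold (a deliberately leaky variant that
reuses whole-matrix statistics is available for comparison).

## Calibration protocols

1. **Uncalibrated** — leave-subject-out; overall accuracy is
   segment-weighted.
2. **Sequential** — each 120 s segment splits into twelve 10 s
   sub-segments; training = all other subjects + the subject's sub-segments
   0..j, test = j+1, each tested sub-segment then joins training; eleven
   evaluation points per segment, indexed by the number of prior
   same-subject sub-segments. The calibration pool resets at every new
   segment (a non-reset variant exists); resetting is what makes the
   x-axis a clean 1–11.
3. **Distant** — at segment granularity, calibration segments are grouped
   by their time distance to the test segment (<1 h, 1–6 h, 6–24 h,
   >24 h); within a bucket, earlier segments are added oldest-first.

Curves report mean, median and the 15th/85th percentiles of per-subject
accuracy per calibration count, as tidy CSV. Every protocol is implemented
as a fold generator, so the absence of train/test leakage is asserted
directly on the index sets.

## Numerical and scale choices

Default experiment sizes are chosen for desk-scale runs: the standard
cohort is 20 subjects × 6 segments (≈ 12,000 beats through the full signal
path, a few minutes end-to-end on one core), and the recovery benchmarks
use a 20-subject noise-free cohort. Key tolerances: fiducial recovery is
assessed at ±2 samples (16 ms at 125 Hz); R-peak matching at ±25 ms under
noise; the exact-arithmetic identities (areas, ratios, z-score round-trip)
at 1e-9 relative.

## Known limitations

* The generator's waveform components are smooth analytic shapes; detector
  robustness to real-world artifact classes (motion, saturation, ectopy) is
  out of scope.
* The PTT feature follows the source definition (ABP systolic peak to PPG
  systolic peak within one beat), which requires the invasive pressure
  channel; in cuff-less deployments it must be disabled
  (`include_ptt: false`), leaving 22 features.
* Reported accuracies are properties of the synthetic regime. They
  replicate the *structure* of the calibration findings (near-chance
  uncalibrated accuracy, a jump with one calibration measurement, gradual
  saturation, decay with calibration distance) — not the numerical values
  of any clinical dataset.
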