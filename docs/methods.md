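# Methods

This note records the models implemented by `hemodyn`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Signals and preprocessing

Raw input is a paired recording: arterial blood pressure (mmHg) and
cerebral blood-flow velocity (cm/s), both uniformly sampled (default
100 Hz) for five minutes per subject and posture. The conditioning chain
is fixed and ordered:

1. **Spline gap repair.** Runs of invalid samples longer than 4 are
   replaced by a natural cubic spline fit on up to 50 valid samples per
   side; shorter runs are left to the Hampel stage. Gaps touching the
   record boundary are unrepairable and raise.
2. **Hampel filter** (window halfwidth 10 samples, threshold 3 scaled
   MADs; 1.4826·MAD is the consistent normal-σ estimate). Edges are
   reflect-padded; on monotone boundary trends the filter may touch edge
   samples, which is accepted.
3. **Zero-phase low-pass:** 4th-order Butterworth at 20 Hz applied
   forward and backward (8th-order magnitude, exactly zero phase).
4. **Beat detection** on BP: end-diastolic minima first (refractory
   spacing 1/max_hr, default max_hr 3 Hz; prominence ≥ 25 % of the
   10–90 % amplitude range), then the upstroke as the steepest rise
   between successive minima. Intervals whose upstrokes violate the
   refractory period — typically a residual artifact notch splitting one
   cycle — are merged before landmarks are finalized.
5. **Beat averaging** over half-open [upstroke_i, upstroke_{i+1})
   intervals, for BP and BFV against the same BP-derived beats.
6. **Beat-domain Hampel** (window 5 beats, 4 MADs). An artifact that
   coincides with a systolic rise can survive the sample-domain filter —
   the window's deviation scale explodes on the steep slope — and a single
   corrupted beat mean would otherwise set the min–max range for the whole
   channel. Screening the beat series closes that hole.
7. **Uniform resampling** of beat means by cubic spline at 0.4 s
   (2.5 Hz). The alternative literal reading of the target rate (0.4 Hz,
   i.e. 2.5 s intervals) would leave only 1–2 samples inside the 3–6 s
   autoregulation-recovery window, so 2.5 Hz is the default and the
   interval is a config field.
8. **Min–max normalization** to [−1, 1]; the output attains both bounds
   exactly. Normalization cancels units, which is what makes the ARI
   invariant to affine rescaling of the raw channels.

## Dynamic pressure→flow models

Four families (FIR, NFIR, ARX, NARX; linear kernel for FIR/ARX, Gaussian
for NFIR/NARX) are fitted by ν-SVR on delay-embedded rows. Training is
one-step-ahead (measured flow in the recurrence slots) on the first half
of the recording; selection uses the Pearson correlation of a free-run
prediction over the second half, seeded with the last `n_v` training
values so the validation flow is never peeked at. ε is not a search
dimension: ν-SVR derives the tube width from ν.

The full grid spans n_p ∈ 1..10 (feed-forward) or 1..8 (recurrent),
n_v ∈ 1..6, C ∈ 2^{−2..14}, ν ∈ {0.1..0.9}, log₂σ ∈ −1..5, stepping
exponents by 2; a reduced grid (n_p ≤ 3, n_v ≤ 2, C ∈ {1, 16}, ν = 0.5,
σ ∈ {1, 4}) is the default for synthetic cohorts, where it recovers the
generating dynamics reliably at a fraction of the cost. Free-run outputs
beyond ten times the normalized range are declared divergent and the
candidate is discarded. The fitted quadratic program has a unique optimum,
so training is deterministic; prediction uses a direct evaluation of the
support-vector expansion (verified against the estimator's own `predict`).

## Autoregulation index

The selected model is driven in free-run mode by a negative pressure step
in normalized units (default: hold at the training mean for 20 s, then
drop by 1.0 — half the normalized range). The recurrent state is first
settled by fixed-point iteration so the pre-step response is constant.
The response is re-expressed in template units: pre-step level 1, scaled
per unit step.

**Plausibility rules.** (i) drop amplitude ≥ 40 % of the pre-step level
(the alternative residual-level ≤ 40 % reading is selectable); (ii) the
late plateau (mean over the last 2 s of the window) lies between the
response minimum and the pre-step level + 10 % of the drop; (iii) the flow
return is visible 3–6 s after the step: within that window the response
has risen from its minimum by at least 10 % of the drop, and the minimum
itself occurs before 6 s. Rule (iii) deliberately reads "return between
3 and 6 s" as *recovery under way by then*: the Tiecks recursion starts
recovering immediately at every non-zero grade, so a rule demanding that
recovery *onset* fall inside 3–6 s would reject every template, while the
chosen reading passes grades 1–9 and fails exactly the no-autoregulation
response. An absent-recovery response (grade 0) fails (iii) only.

**Matching.** Templates are the ten Tiecks responses to the same step on
the same grid. Response and templates are shape-normalized — rescaled to
span [minimum, pre-step level] — before the mean-squared-error match over
0–10 s post-step; the grade is the argmin, ties toward the lower grade.
Shape normalization is used because the grade is encoded in the recovery
trajectory, while the response gain in doubly-min-max-normalized
coordinates depends on which frequencies dominate a particular recording;
matching raw amplitudes would confound the two. Amplitude adequacy is
enforced separately by rule (i). Optional quadratic interpolation around
the argmin yields a fractional grade (off by default).

**Model discard.** A high validation CC does not guarantee a
physiological step response. Grid candidates are therefore revisited in
decreasing CC order and the first one passing the gate supplies the
grade; if none of the top twelve passes, the best-CC model's estimate is
reported ungraded and flagged.

The Tiecks parameter table (T, D, K per grade) is embedded as a versioned
constant transcribed from the original formulation, the critical closing
pressure defaults to 12 mmHg (a mid-range literature value, configurable),
and the forward-Euler recursion requires dt < T (enforced).

## Wavelet entropy and statistical complexity

Detail energies `E_j` of an m-level periodized DWT (default `db4`;
m = floor(log₂ n) − 2, additionally capped by the wavelet's maximum useful
depth) are normalized to relative energies `p_j`, excluding the
approximation band by default — slow trend energy would otherwise dominate
every distribution (inclusion is a flag, and the choice is recorded in
outputs). From `p`: H (nats) and H_norm = H/ln m; disequilibrium Q with
Q₀ = m/(m−1) (Euclidean) or 1/arccos√(1/m) (Wootters), both exactly 1 at
a point mass; complexity C = H_norm·Q (the raw-H product is a flag).

A caution worth recording: over octave bands, *white* noise is not the
maximum-entropy signal — its energy halves per level, giving H_norm ≈ 0.73
at m = 6. The disordered corner of the complexity–entropy plane belongs
to 1/f noise (equal energy per octave); the tests assert both facts, the
first against the analytic dyadic distribution.

## Group statistics

The repeated-measures ANOVA is the balanced one-way within-subject form,
F = MS_condition / MS_(condition×subject), implemented directly (and
cross-checked against an established implementation in the tests) so that
a 10,000-draw within-subject permutation test remains cheap. The
Greenhouse–Geisser ε and corrected p are computed alongside; the
uncorrected p is the default display. Tukey comparisons reuse the ANOVA
error term with studentized-range p-values. AUC uses the Mann–Whitney
identity with ties counted half; because posture-pair class polarity is a
labelling convention, the oriented AUC max(A, 1−A) is reported with the
orientation flagged. Hemisphere values are averaged into one value per
subject only when a paired test (t or Wilcoxon, chosen by Shapiro–Wilk on
the differences) finds no difference at α = 0.05; otherwise both sides are
retained and flagged. The synthetic generator emits a single merged flow
channel, so the merge rule is exercised by unit tests rather than the
pipeline.

## Synthetic generator: what it emulates, and not

Per subject and posture the generator produces:

- **BP**: a clipped raised-cosine pulse train (systolic fraction 0.35,
  pulse pressure 40 mmHg, diastolic floor decaying 8 mmHg across the
  cycle so the end-diastolic minimum stays pinned to the pulse foot),
  respiratory (0.25 Hz, 1.5 mmHg) and Mayer (0.10 Hz, 2.5 mmHg) waves,
  very-low-frequency drift (random phases in 0.01–0.08 Hz, SD 3 mmHg),
  1/f variability scaled by `noise_sd`, and isolated ±5 SD artifact
  spikes (≤ 3 consecutive samples) at `outlier_rate`. Posture baselines
  default to young-adult group means (lay/sit/stand 74.96/81.45/84.81
  mmHg; flow 59.27/52.88/53.50 cm/s). Heart rate is drawn per subject
  from 0.9–1.25 Hz unless fixed.
- **BFV**: the Tiecks recursion at the chosen grade driven by the
  *physiologic* pressure (before artifact injection — spikes are sensor
  error, not physiology), scaled to the posture baseline, plus white
  measurement noise.

The VLF drift is not decoration: the autoregulation plateau (steady-state
gain 1−K) is only observable below the autoregulation corner frequency
(~0.05–0.15 Hz). Pressure input with energy only at the respiratory and
Mayer lines carries almost no grade information, and no identification
method can recover what the input does not excite.

Not emulated: baroreflex closed-loop coupling, CO₂ reactivity,
heart-rate variability beyond a fixed per-subject rate, beat-morphology
variation, and any pathology. Passing tests therefore demonstrate that the
pipeline recovers the Tiecks-style dynamics and band-energy structure it
is pointed at — not that it is robust to every failure mode of clinical
recordings.

## Problem sizes and tolerances

The test suite and the acceptance script run cohorts of 10 subjects per
grade (grades 2, 5, 8; 300 s at 100 Hz; 2 % noise) with the reduced NARX
grid — sizes chosen to give stable Monte-Carlo statistics on a single
CPU in minutes. Grade recovery within ±1 is the criterion (discrete
10-level matching from spontaneous data has an inherent ±1 granularity);
typical runs recover ≥ 90 %. Monte-Carlo checks use 100–200 seeds;
exact algebraic identities (Parseval, F = t², point-mass normalizations)
are asserted at 1e-9..1e-12; the Euler discretization consistency between
100 Hz and 50 Hz is held to 1 % RMS.

## Known limitations

- Forward-Euler integration of the Tiecks recursion matches the classic
  discrete formulation but is first-order accurate; template and model
  responses are always generated at the same dt so discretization bias
  cancels in the match.
- One-step-ahead ν-SVR training weights the fit toward the dominant
  spectral bands; on recordings whose VLF content is weak the recovered
  grade degrades (by design of the estimator, not a bug).
- The beat detector assumes pressure-like morphology (steep rise, decaying
  diastole); it is not an ECG-grade detector.
- Tukey p-values assume the pooled within-subject error term; with k = 3
  conditions and small n they are approximate under sphericity violations
  (ε is reported so users can judge).
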