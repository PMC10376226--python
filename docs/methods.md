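# Methods

`hopwave` implements a time–frequency analysis pipeline for surface EMG
recorded during a one-leg hop-for-distance test, together with the
statistical machinery used to decide whether muscle-activation patterns
differ between limbs or between an ACL-reconstructed (ACLR) cohort and
healthy controls, and to relate clinical outcomes to an MRI-based knee
degeneration (WORM) score. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic data generator does and does not emulate.

## Signal model and conditioning

A trial consists of seven EMG channels (GM, GL, TA, VM, RF, BF, ST)
sampled at 3000 Hz, vertical ground reaction force (vGRF) on the same
clock, and ankle vertical velocity plus knee flexion at 125 Hz (clock
ratio 24). Conditioning removes 60 Hz line interference and every
harmonic below the band edge (60, 120, …, 660 Hz) with second-order IIR
notches of 4 Hz absolute bandwidth, then restricts the signal to the
7–700 Hz physiological window with a 4th-order Butterworth band-pass.
All filters are applied forward–backward (zero phase) with reflect
padding of up to 1024 samples, because burst *timing* feeds both the
phase segmentation and the classifier; a causal realization would lag
envelopes by several milliseconds. No filter family or order is
canonical for this step; the orders and bandwidths here were chosen to
meet explicit, testable contracts — ≥ 30 dB attenuation at each notched
harmonic, ≤ 1 dB loss for tones ≥ 4 Hz away from a notch and for
mid-band content — and those contracts, not the realization, are what
the test suite pins down. `condition_signal` applies the whole cascade
in a single pass of stacked second-order sections; this is numerically
equivalent to composing the two stages (LTI sections commute) and is
verified against the sequential composition in tests.

## Wavelet filter bank

The bank contains 14 non-linearly scaled Gaussian-shaped wavelets
defined directly in the frequency domain:

    cf(j) = (1/scale) · (j + q)^r,   j = 0 … 13,
    W_j(f) = (f / cf_j)^(cf_j·scale) · exp((1 − f/cf_j) · cf_j·scale)

with scale = 0.3, q = 1.45, r = 1.959 — the standard constants of this
bank family. The centers run from 6.90 Hz to 623.8 Hz, strictly
increasing with decreasing ratio (the "non-linear scaling"), and each
wavelet has unit gain at its own center. The canonical bank of this
family has 11 wavelets; the count is extended to 14 by continuing the
same scaling rule upward, which keeps every center inside the 7–700 Hz
conditioning band. The constants are arguments of `build_filter_bank`,
so a re-spaced alternative can be swapped in.

Band intensity is the squared magnitude of the analytic representation
of the band-filtered signal: the FFT of the (zero-padded) signal is
multiplied by 2·W_j on positive frequencies and zero elsewhere, and the
inverse transform's magnitude is squared. This estimate is nonnegative,
time-resolved, lag-free, and scales quadratically with amplitude —
exactly the properties the normalization and averaging steps require.
Padding to `next_fast_len(2n)` suppresses circular wrap-around; the pad
is discarded before returning.

## Hop-phase segmentation

Four events split a trial into take-off `[t0, t1)`, airborne `[t1, t2)`
and landing `[t2, t3]` (half-open so the frames partition the record;
t3 inclusive):

* **t2 (contact)** — first sample where vGRF rises above 50 N
  (strictly greater, with the previous sample at or below threshold).
* **t3 (impact peak)** — first occurrence of the post-contact maximum;
  an error if the force never falls again (no landing transient).
* **t1 (take-off)** — minimum ankle vertical velocity strictly before
  the motion-capture image of t2, mapped back to the EMG clock by the
  rounded clock ratio.
* **t0 (movement onset)** — the later of two onsets: summed squared
  EMG (smoothed by a 10 ms causal moving average) and knee-flexion
  deviation from its static baseline, each crossing
  baseline mean + 3·SD for a sustained run (25 ms for EMG, 2 samples
  for the 125 Hz knee channel). The baseline window is the first 0.4 s
  of quiet standing.

The onset detector deliberately uses a *broadband* short-window power
envelope rather than the wavelet total intensity: the low-frequency
wavelets spread envelope energy backwards by tens of milliseconds
(their time support at 6.9 Hz exceeds 100 ms), which would make a
±1-sample onset contract impossible. The sustained-run rule and
k_sd = 3 are standard onset-detection conventions; the qualitative
definition ("EMG activity and knee flexion increase from near-zero
baseline") fixes neither, so both are configurable. On noise-free
synthetic trials all four events are recovered within ±1 sample; at
the generator's default noise level t1–t3 are exact and t0 is within
±10 ms (measured ≈ 4–8 ms late, the threshold-crossing delay of a
rising envelope).

## Pattern normalization

Each phase of each band is linearly resampled to 100 frames over
normalized phase time (endpoints inclusive, so constants and ramps
survive exactly), giving a 14 × 300 map per muscle per trial. Each
band is then z-scored (mean 0, SD 1) over its 300 frames. Two readings
of the normalization sentence in the source protocol are possible —
per-trial over frames, or across trials at each frame; the per-trial
reading is adopted because the across-trial reading would force group
means toward zero and contradict the subsequent averaging step. Warping
precedes z-scoring (the order is recorded in exported map metadata);
the alternative order differs only through the interpolation weights
and was not pursued. The composition intensity → warp → z-score is
invariant to an overall EMG gain — the stated purpose of the
normalization (removing baseline intensity differences between
subjects) — and this invariance is tested to 1e-6 at ×10 gain. A band
with zero variance (or variance at rounding-noise level relative to
its mean) cannot be scaled; it is set to all zeros and a warning is
emitted. The [0, 1] min–max rescale in `export_map` exists only for
display and never feeds classification; an all-constant map rescales
to zeros by convention.

## Classification

Per muscle, patterns are flattened row-major (4200 features whole-hop,
1400 per phase) and classified with 1-nearest-neighbor under
leave-one-out cross-validation for three pair-wise comparisons:
control index vs control contralateral, ACLR surgical vs ACLR
contralateral, and ACLR contralateral vs control index. Euclidean
distance is the default (none is canonical for this task); ties at
exactly equal distance resolve to the lowest sample index — documented
because a hand-checkable toy example (alternating labels on a line)
depends on it. The implementation is deliberately explicit (a masked
distance-matrix argmin, not a library classifier) so the tie rule and
fold logic are visible; an independent brute-force enumeration oracle
verifies it exactly on random batteries of ≤ 8 points.

Two cross-validation units are first-class: `trial` (leave one
trial-limb record out) and `subject` (leave all of a subject's trials
out). Subject-level folds remove any same-subject information from the
reference set, at the cost of a small systematic depression of null
rates (holding out a subject depletes its own class by three records,
so under the null the nearest neighbor is slightly more often
opposite-class: ≈ 47.8 % expected rather than 50 % at cohort size
12 + 11). Trial-level folds match the per-trial denominators of the
reference analysis (62/63/69 records per comparison) and keep the null
within about half a percent of chance; they are used for the
calibration checks below. The library default is `subject`
(conservative with respect to leakage); both are exposed.

## Significance: the critical classification rate

Under the null hypothesis of indistinguishable classes, the number of
correct LOOCV classifications k out of n is modeled as Binomial(n, ½).
The critical classification rate is the smallest k/n with a test
p-value below the Bonferroni-adjusted level α/m. Two conventions are
implemented, because they disagree at small n and each is defensible:

* **exact** — binomial tail P(X ≥ k);
* **normal-approximation** — one-sided z-test of the proportion,
  z = (k/n − ½)/√(¼/n), no continuity correction.

For n = 23, α = 0.05, m = 3 (one-sided): the normal approximation
gives k = 17, i.e. a critical rate of 73.9 % (z = 2.294, p = 0.0109 <
0.0167, while 16/23 gives p = 0.0303); the exact test gives k = 18.
Every verdict records which convention produced its threshold.
Verdicts use a strict inequality (a rate exactly at threshold is not
significant). A power utility reports the smallest true success
probability detectable with given power at the critical k; it is
informational only and never used as a threshold. LOOCV outcomes are
not strictly independent Bernoulli draws (shared reference sets couple
the held-out predictions), so the binomial model is an approximation;
at cohort sizes used here the measured null dispersion is ~10–15 %
above binomial, which the calibration test absorbs by checking a
replicate-level pass rule rather than each cell independently.

## Outcome statistics

Pairwise association between outcomes (thigh-girth side-to-side
difference in cm, KT-1000 laxity difference in mm, hop-distance ratio
in %, Tegner grade) and the summed WORM score uses two-tailed Pearson
correlation with pairwise deletion of missing values; the signed r and
r² are reported separately and no multiplicity adjustment is applied
(mirroring the reference analysis). Prediction uses bidirectional
stepwise OLS: forward entry by the smallest coefficient p-value below
α_enter = 0.05, backward removal of any included term above
α_remove = 0.10 (defaults; neither threshold is canonical), ties
broken alphabetically, with a full step log. α_remove ≥ α_enter
guarantees termination. Near-perfectly collinear candidate pairs
(|r| > 0.9999) raise an error naming the pair. Cohort summaries report
group means and sample SDs (n−1) to one decimal; the packaged cohort
table reproduces the published patient summary (age 34.7 ± 9.9 years,
follow-up 11.9 ± 1.3 years) exactly.

## Synthetic cohort generator

The generator manufactures the study's structure — (12, 11) subjects
per group by default, two limbs each, three trials per limb, with an
optional missing-trial rate — with known ground truth everywhere.

Per trial, each muscle fires one or two bursts of band-limited Gaussian
noise (Gaussian spectral window, σ = 25 Hz, around a muscle-specific
centroid of 90–140 Hz) under compact-support envelopes, so the quiet
baseline is exactly zero in the noise-free limit. Burst timing follows
a plausible hop choreography (quadriceps from movement onset and at
landing; calves late in take-off and at landing; hamstrings airborne;
TA pre-landing). Movement-onset bursts (VM, RF) are pinned to start
exactly at t0 with a fast ~30 ms attack; other bursts use Hann
envelopes and never start before t0. 60 Hz line interference
(0.05 mV) and white noise (0.01 mV) are added; burst peaks are ~1 mV,
i.e. realistic surface-EMG SNR. Force is zero until a 5-sample ramp
that crosses 50 N exactly at t2, rises half-cosine to a ~1600 N peak
at t3, and settles to body-weight level; ankle velocity attains its
unique pre-contact minimum exactly at the mocap image of t1; knee
flexion leaves its static baseline at t0's mocap image (its ramp
starts one mocap sample earlier, so quantization does not bias the
detected onset late). t0 and t1 are constructed on the 24-sample
mocap grid.

Group differences are injected only for the ACLR group (both limbs,
with a small extra factor on the surgical limb): per unit of
`effect_size`, targeted bursts get a ×e^0.45 amplitude factor, +15 ms
latency (never applied to onset-pinned bursts, which anchor t0), and
+6 Hz centroid shift, optionally restricted to chosen muscles and
phases. The scaling was calibrated during design so that
`effect_size = 3` restricted to VM/RF take-off produces a group-mean
pattern shift of ≈ 2.5–3.5 z-units at its peak — comfortably above the
1.5-unit bar the effect-recovery check conditions on — and at
`effect_size = 0` the group label has no influence at all (the same
substream yields bit-identical channels under either label).

Between-subject variability is deliberately weak (log-amplitude SD
0.024, latency SD 1.5 ms, centroid SD 0.9 Hz at the default
`subject_jitter = 0.3`) relative to trial-level jitter (amplitude SD
0.15 log units, latency 8 ms, centroid 5 Hz, width 8 %, phase
durations 6 %): the null-calibration property requires classification
rates to be approximately binomial around chance, which fails if
trials of one subject cluster strongly. This is the generator's main
departure from real cohorts, where subject signatures are strong; see
limitations. Randomness derives from one master seed with per-(subject,
limb, trial) substreams keyed by CRC-32 hashing, so single trials can
be regenerated in isolation.

Subject outcomes are simulated with a configurable linear link
worm = 15 − 20.8·girth + ε (ε ~ N(0, 3), girth rounded to the 0.5 cm
tape resolution, scores floored at zero), which a stepwise regression
recovers; the other outcomes are drawn near the published cohort's
ranges and are (by construction) unrelated to the score.

## Problem sizes and seeds in the checks

The replicate-based checks use cohorts of (12, 11) subjects × 2 limbs
× 3 trials (138 trials, 69 records in the group comparison), 20
replicates with consecutive fixed seeds, on the full raw-signal
pipeline (generation → conditioning → wavelets → detected events →
patterns → classification). The null check requires ≥ 6 of 7 muscle
rates inside the exact central 95 % binomial band in ≥ 18/20
replicates — seven simultaneous 95 %-coverage checks cannot all be
required at once, since ~30 % of replicates would show at least one
excursion even under perfect calibration. The regression-recovery
check runs 200 outcome-only replicates at n = 11. The stepwise null
check (no true predictors) uses 30 replicates at n = 50.

## Known limitations

* The binomial null for LOOCV rates is approximate (see above); the
  generator is calibrated so the approximation is adequate at the
  default study size, not in general.
* The generator emulates burst timing/frequency/intensity structure,
  line interference, and baseline noise — not motion artifacts,
  electrode lift, crosstalk between channels, force-plate noise, or
  strong subject signatures. Passing tests therefore demonstrate the
  pipeline's correctness and sensitivity under controlled conditions,
  not field performance on real recordings.
* Kinematic channels are stylized (cosine segments), adequate for
  event-detection contracts only; no musculoskeletal realism is
  intended or provided.
* The exact stepwise variant and its thresholds in the reference
  analysis are unknown; the bidirectional procedure here is one
  defensible reconstruction and every run logs its steps.
* With `cv_unit="subject"` and the small default cohort, null rates
  sit ≈ 2 % below chance for structural reasons (class depletion);
  thresholds compared against 50 % are slightly conservative there.
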