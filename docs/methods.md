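# Methods

This note records the models, numerical choices and open design decisions
behind `hrv3state`, in the spirit of a statistical package's methods
appendix. It states no result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and preprocessing

The pipeline's central object is the R-R interval series: beat-to-beat times
in ms with onset times in s and per-interval quality flags. ECG input is
plain CSV (`time_s, voltage`, header required, UTF-8, `.` decimal separator)
with the sampling rate inferred from the median sample spacing and more than
1 % timing jitter rejected, or a minimal text-layout record
(`<name>.hea` + `<name>.csv`). R peaks are detected with a
Pan–Tompkins-style detector: 5–25 Hz band-pass (2nd-order Butterworth,
forward–backward), squared derivative, 150-ms moving-window integration,
threshold at 25 % of the energy signal's 99th percentile, 250-ms refractory
period, and refinement of each candidate to the dominant filtered deflection
within ±60 ms. The detector is validated against the simulator's
ground-truth beat times (≥ 99 % recovery within 20 ms at ~20 dB SNR on
five-minute records) rather than against an annotated clinical database,
which bounds what the tests show about real ECG: morphology variants,
baseline wander and electrode artifacts are not represented.

**Artifact rule.** Intervals outside 273–1500 ms are non-physiological for
this population (paroxysmal/ectopic beats). An isolated out-of-range
interval is replaced by the mean of its two neighbouring accepted intervals
and flagged `replaced`; an out-of-range interval at either series end lacks
two neighbours and is dropped (`excluded_boundary`, counted). Two or more
*consecutive* out-of-range intervals are outside the correctable class and
raise an error instead of being silently interpolated — in the intended
measurement setting such trains indicate a recording that should be redone,
and interpolating them would fabricate spectral content. The cleaning rule
is idempotent because the replacement (a convex combination of in-range
values) is always in range.

**Resampling.** Spectral estimation needs a uniform series, so the
interval-versus-onset-time curve is interpolated by a cubic spline (linear
fallback below 4 beats) on a uniform grid at the *mean heart rate*
(1000/mean R-R in Hz), computed once over the whole cleaned recording, not
per state. At typical rates (~1.2 Hz) the Nyquist frequency (~0.6 Hz)
comfortably covers the 0.4 Hz upper analysis edge, and spline attenuation of
a 0.25 Hz component is negligible (the variance-recovery test bounds it at
< 5 %).

## Maximum-entropy spectral trend

Each analysis frame covers the preceding 30-s window, stepped every 2 s; the
first frame is emitted 30 s after the tachogram start, so a frame
timestamped t summarises data in (t − 30, t]. Within a frame:

- the window mean is subtracted (no linear detrend — minimal intervention;
  configurable behaviour was considered and rejected as an extra untestable
  degree of freedom);
- an AR model of order 16 is fitted by the Burg lattice recursion. Order 16
  on ~36-sample windows follows the common practice of an order around n/2
  being too many and n/15 too few for line-like HRV spectra; 16 resolves two
  sinusoidal components (0.1 and 0.3 Hz) to within 7 % of their analytic
  powers in the resolution test and keeps the full-band integral within 0.1 %
  of the window variance on coloured-noise windows. The order is an explicit
  argument everywhere because results depend on it;
- the one-sided PSD S(f) = 2 σ² Δt / |1 − Σ c_k e^{−i2πfkΔt}|² is evaluated
  and LF = [0.04, 0.15) Hz and HF = [0.15, 0.4] Hz are integrated by the
  trapezoid rule (the shared 0.15 Hz edge belongs to HF);
- heart rate is 60000 / mean(window R-R), taken from the raw window, not
  from the AR model;
- LF/HF is recorded as missing (NaN) when HF is zero, e.g. for a constant
  window.

**Numerical subtlety — near-singular spectra.** A nearly deterministic
oscillation drives Burg poles within machine precision of the unit circle;
the resulting Lorentzian peaks can be narrower than any uniform grid spacing
while carrying finite power. Band integrals therefore use a *peak-refined
grid*: the base 1024-point uniform grid plus log-spaced offsets around each
pole frequency from 10⁻² of the peak half-width (1 − |pole|)/(π Δt) outward.
The exact peak centre is excluded (its denominator can underflow to zero);
should a base grid point still coincide with a pole, the infinite value is
capped at the largest finite PSD sample. With this grid the per-frame HF of
a pure ±50 ms, 0.25 Hz R-R sinusoid is recovered within 4 % of the analytic
A²/2 = 1250 ms². Stability is certified by the reflection coefficients
(|k| < 1 by construction of the Burg recursion); a root-radius check with a
10⁻⁶ tolerance covers hand-built models.

The proprietary analysers used in clinical deployments of this paradigm do
not document their model order or detrending, so exact numeric agreement
with any specific device is not claimed — the validation targets are closed
forms, analytic signal powers and an independent lattice-recursion oracle.

## State averaging and features

States are contiguous Rest → Task → After with defaults 60/100/60 s
(annotated boundaries take precedence when present). A frame on a boundary
belongs to the later state (half-open intervals). Each index is averaged
over frames with t ∈ (state_start + 30, state_end]: since a frame at t uses
data in (t − 30, t], requiring t > start + 30 guarantees the average
contains no data from the preceding state — the protocol's decontamination
rule, which the step-profile test verifies directly. For the 100-s task this
leaves a 70-s window, i.e. 35 frames at the 2-s step.

The per-state LF/HF value is the mean of per-frame LF/HF over the averaging
window, not the ratio of the state-mean LF to state-mean HF; published
summary tables cannot disambiguate the two conventions, and the trend-based
protocol computes LF/HF every 2 s, which favours the per-frame mean. The
alternative is one line of user code (ratio of the returned state means) if
ever needed.

Responsiveness ratios divide Task and After averages by the Rest average
(guarded against a zero Rest value), and the feature vector is the fixed
12-tuple HF, LF, LF/HF, HR × Rest level, Task/Rest, After/Rest — the
ordering of the discriminant equation's coefficients a–l.

Two protocol validity checks are implemented as data rules: the EPDS
screening cutoff (positive iff score ≥ 9, configurable) and the breathing
band check (9–24 breaths/min, i.e. 0.15–0.4 Hz; outside it HF no longer
reflects respiratory parasympathetic modulation and a warning is issued).
Reported percentages are rounded half-up to one decimal, matching the
presentation convention of clinical tables.

## RNG task index

The task statistic is Evans' digram-redundancy index

RNG = Σ_{ij} n_ij ln n_ij / Σ_i n_i· ln n_i·,

with n_ij the count of ordered adjacent digit pairs and n_i· its row sums:
0 when every adjacent pair is distinct, 1 for a constant sequence. A naive
"fraction of repeated adjacent digits" reading has expectation ≈ 0.1 under
uniform randomness, far below the 0.3–0.45 range reported for human
subjects in this protocol's literature, whereas the digram-redundancy form
lands in it; the naive metric remains available via
`rng_index(seq, method="repeat_pair")`. The index is invariant under digit
relabelling and bounded in [0, 1] (property-tested).

## Discriminant

Fisher's two-group solution with equal priors: coefficients
w = (S_pooled + λI)⁻¹ (μ_f − μ_l), threshold at the midpoint
w·(μ_f + μ_l)/2, so D > 0 supports the first-named group and the training
means project to ±Md²/2. With 12 features and clinical group sizes of
12–33, S_pooled is ill-conditioned; the study-level runner defaults to a
ridge of 10⁻⁶ × the mean pooled diagonal and falls back to the pseudo-inverse
past condition number 10¹². Features enter in raw units (no
standardisation), so coefficients carry the inverse units of their feature.
Ties (D = 0) count as the negative class — exact zeros are measure-zero but
the partition into D > 0 / D < 0 must be deterministic. Evaluation is by
resubstitution (no cross-validation), which matches how screening
performance is conventionally reported for this protocol and overstates
generalisation accordingly. Separation is Md = √((μ_f − μ_l)ᵀ
(S_pooled + λI)⁻¹ (μ_f − μ_l)) with the standard two-sample Hotelling T²
F-approximation, T² = (n₁n₂/(n₁+n₂))Md², F = T²(n₁+n₂−p−1)/(p(n₁+n₂−2)) on
(p, n₁+n₂−p−1) degrees of freedom; when n₁+n₂ ≤ p+1 the p-value is reported
as missing rather than fabricated.

## Synthetic cohort

The generator exists because raw recordings for this kind of clinical
study are not distributable; it defines the package's study conditions.

**IPFM heartbeats.** An instantaneous rate m(t) = (1 + x(t)/RR̄(t)) ·
1000/RR̄(t) beats/s is integrated on an 8-Hz grid and a beat fires at each
integer crossing (crossing times linearly interpolated). The modulation x(t),
in ms of R-R deviation, sums one LF sinusoid (0.1 Hz default), one HF
sinusoid (0.25 Hz default, the respiratory band) and broadband noise (white
at 2 Hz, interpolated). Because each interval averages the rate over its own
duration τ, beat-domain amplitudes are attenuated by sinc(πfτ); the drive
amplitudes are pre-compensated by that factor so `lf_amp`/`hf_amp` are
realised as actual peak R-R deviations — a sinusoid of amplitude A then
contributes A²/2 ms² of measured band power, the identity all recovery tests
rest on. State parameters step at the Rest→Task and Task→After boundaries
with a 5-s linear crossfade: instantaneous steps would inject broadband
artifacts beyond what the protocol's 30-s skip rule is designed to absorb,
while the crossfade keeps the skip rule itself the tested mechanism.

**Group presets.** Per-state amplitudes are set analytically from published
group×state band-power means (A = √(2·power)) and mean R-R from heart rate
(60000/HR): e.g. controls rest near 526 ms² HF / 73 bpm and suppress HF to
~35 % during the task; AJD rebounds to ~1.6–1.9× resting HF after the task;
PPD shows a flat HF task response with elevated resting LF/HF. Broadband
noise defaults to 8 ms — small against the sinusoid amplitudes (~3 ms² of
HF-band power) so analytic recovery targets stay sharp, while keeping
windows from being numerically degenerate. LF/HF is not controlled
independently (it falls out of the LF and HF amplitudes), so group LF/HF
levels reproduce the ratio of the power targets, not published mean-of-ratio
values — the qualitative ordering (PPD ≫ control at rest) is preserved and
is what the study-level tests assert. Between-subject variation multiplies
amplitudes lognormally (unit mean, cv = 0.2 by default; one shared
multiplier per index plus a smaller per-state wobble so response ratios
vary realistically) and shifts mean R-R normally; EPDS scores are drawn
below the cutoff for controls and at/above it for patient groups. Digit
sequences come from a Markov chain whose repeat bias per group (0.28 / 0.37
/ 0.40) was calibrated once by Monte-Carlo sweep to land the cohort-mean RNG
index near published group means (~0.34 / 0.40 / 0.42).

**What passing does not show.** The simulator has two spectral lines plus
broadband noise per state — no respiratory frequency drift, no baroreflex
LF–HF coupling, no 1/f trend, no arrhythmia. Recovery and classification
results on it validate the *estimator and pipeline mechanics*, not clinical
screening performance on real cohorts; resubstitution accuracy on synthetic
cohorts whose separation is built in (≥ 85–100 % at 40/group) says the
pipeline preserves that separation, nothing more.

## Problem sizes and determinism

Default test and acceptance sizes: 220-s records (the paradigm's length),
30-s/2-s windows, 40 subjects per group for study-level checks, 100-digit
sequences. All randomness flows through `numpy.random.default_rng` seeded
explicitly; a fixed `SimConfig` reproduces byte-identical cohort CSVs, and
the acceptance script derives every stream from its `--seed`.

## Known limitations

- No multi-lead ECG, arrhythmia handling, device acquisition, FFT/Welch
  spectra, time-domain HRV indices or cross-validation (all deliberately out
  of scope).
- The published discriminant coefficients of the motivating protocol are
  not printed anywhere and cannot be reproduced; models are refit from data.
- The R-peak detector is tuned for clean, template-like QRS morphology.
- The breathing-band rule is a numeric check only; respiration itself is
  neither recorded nor simulated as a time series.
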