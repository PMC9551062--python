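# Methods

## Signal model and canonical representation

The pipeline's sole raw input is uniformly sampled tri-axial wrist
acceleration. The canonical unit is the gravitational unit g and the
canonical rate 100 Hz, because every filter constant and window length in
the method is stated at that rate; other rates in [20, 1000] Hz are
linearly interpolated once at ingest. Unit auto-detection assumes m/s²
when the median vector magnitude exceeds 4 (a worn, mostly-resting wrist
reads ≈ 1 g or ≈ 9.81 m/s²; 4 splits the two regimes with wide margin).
Timestamps are carried as seconds from an absolute start; day boundaries
are local midnights.

From the axes four per-sample channels are derived:

- `en_crude = √(x²+y²+z²)`;
- `en_static_removed = en_crude − ⟨en_crude⟩₆₀ₛ`, a centred 60-s moving
  mean with shrinking edges (the first/last 30 s average whatever samples
  exist). A centred window was chosen over a trailing one so the residual
  is phase-aligned with the events it modulates; the alternative mainly
  shifts edge behaviour.
- `en_lowpass`: 5th-order Butterworth low-pass at 20 Hz;
- `en_band`: 4th-order Butterworth band-pass, 0.25–2.5 Hz — the band
  containing stride (~0.5–1.2 Hz) and step (~1–2.4 Hz) frequencies. A
  stated lower passband edge only makes sense for a true band-pass, so
  that is what is implemented.

All filtering is zero-phase (forward–backward), so detected step-event
times are not phase-shifted relative to the raw signal; group-delay
compensation would otherwise bias step times by a filter-dependent constant.
Edge effects are confined to the first and last 60 s, and recordings under
120 s are refused (the static mean is undefined on any interior sample).

## Non-wear and sleep

Non-wear is a long stretch in which the device lies still: per-axis
standard deviation at or below 13 mg on all three axes, sustained for more
than 50 minutes. The SD is evaluated in 10-minute windows stepped by
1 minute (the convention of the large-cohort accelerometry pipelines this
rule comes from); a flagged interval runs from the first qualifying
window's start to the last one's end, which localises a 60-minute constant
block to within one step and rejects a 49-minute one. The SD is per-axis
rather than on the norm: a still device has near-zero variance on each
axis, while norm-based SD can miss slow rotations.

Sleep-period detection is a deliberately simplified stand-in for
posture-based sleep algorithms: the arm elevation angle
`atan2(z, √(x²+y²))` is summarised in 5-s medians, stretches whose
successive medians change by less than 5° for at least 30 min are
candidates, and the longest candidate per 24-h stretch is that night's
sleep-period window. This captures the core signal (a sustained invariant
arm posture) while staying self-contained; the exclusion interface is
pluggable, so a validated external sleep algorithm's mask can be applied
instead. Excluded samples (non-wear ∪ sleep) never enter windowing.

## Windows and features

Wear-time signal is tiled into non-overlapping 4-s windows (400 samples);
a tile is valid only if every sample is usable, so tiles straddling an
exclusion boundary are dropped rather than half-filled, and a partial tail
is discarded. The window length is deliberately not configurable: it is
short enough to resolve the brief walking bouts that dominate daily life
and all downstream definitions (bout = run of windows) depend on it.

The named core feature set (17): mean, SD, 25th/50th/75th percentile of
the static-removed and crude norms (10); pairwise Pearson correlations of
the raw axes (3); and four autocorrelation-shape features of the band
channel — the normalized first-peak coefficient, its time lag, and the
ratios of the first to the second and third peaks. Percentiles use linear
interpolation. The autocorrelation is normalized by the zero-lag value
with *unbiased* (overlap-count) scaling: a strictly periodic signal then
scores ≈ 1 at its period regardless of window length, which is the
established convention for gait regularity and the only scaling under
which a pure in-band sinusoid attains a near-unity peak inside a 4-s
window (the biased estimator caps it at 1 − lag/T ≈ 0.875 at 0.5 s).
Features that are undefined for a window — correlations of a constant
axis, peaks of a flat autocorrelation — are null, never zero or silently
propagated NaN; matrix assembly for the classifier imputes them to 0.

An extended set (axis summaries, jerk RMS, spectral band powers, dominant
frequency, spectral entropy, zero-crossing rates, higher moments) brings
the default dimensionality to 54. The original method selected 54 of 99
features by backward elimination; the full 99-item inventory is not
public, so the extended set is this package's own documented choice, with
the named 17 always present and the list config-driven. `backward_select`
implements the reduction itself: greedy elimination by permutation
importance aggregated over subject-partitioned folds, deterministic given
its seed.

## Activity classification

Stage one is a six-class RBF-kernel SVM (walking with arm-swing, other
complex walking, running, stationary — vehicle travel included —
unspecified arm activity while static, unspecified arm activity while
walking); stage two refines "other complex walking" into five arm-carriage
sub-modes (pocket, texting, phone call, shoulder bag, briefcase) and is
trained on true walk-other windows, with the cascade applied to predicted
ones at inference. Features are standardized on the training folds only;
the "medium Gaussian" kernel width of the original toolchain maps to a
kernel scale of √(n_features), i.e. `gamma = 1/n_features` on standardized
inputs. Class weights are inverse-frequency, since daily-life data are
dominated by stationary windows. Multi-class handling is one-vs-one, the
standard SVM reduction.

Cross-validation always partitions subjects, never windows: a subject's
windows are strongly correlated, and window-level folds overstate accuracy.
Fold assignment is a deterministic function of the sorted subject ids and
the seed alone, so no reordering of the data can move a subject across
folds; training refuses any class present in fewer than two subjects,
because a leakage-safe validation of that class is then impossible.
Evaluation reports per-class sensitivity (row-normalized confusion
diagonal) and precision (column-normalized), with nulls for classes absent
from truth or predictions.

Windows labelled "unspecified arm activity while walking" count as walking
for bout assembly and gait quantity, but are excluded from gait-quality
and speed computation, which are defined on arm-swing walking.

## Step detection

Within a walking bout (a maximal run of consecutively-timed walking
windows; one non-walking window ends a bout, though a gap tolerance is
exposed for sensitivity analyses), candidate step events are the local
extrema of the band channel, pruned by three rules:

1. **amplitude** — maxima must exceed +θ and minima fall below −θ, where
   θ = 0.3 × the rolling 4-s RMS of the band channel. The factor is a
   package default (the original threshold is not published numerically):
   0.3 sits well below the ~√2 peak-to-RMS ratio of a near-sinusoidal
   gait band, so genuine steps always clear it, while baseline noise
   between bouts does not;
2. **alternation** — maxima and minima must strictly alternate; of two
   same-type neighbours the more extreme survives (ties: the earlier);
3. **step-time consistency** — successive maxima spaced more than 30%
   tighter than the per-window autocorrelation step-time estimate lose
   their weaker member, which rejects isolated artifact spikes.

Retained maxima are the steps: at the wrist the norm peaks once per step
(twice per arm-swing cycle). Counting both extrema would double-count; the
maxima-only reading is the package's documented choice. The
autocorrelation step-time estimate itself is the lag of the first local
maximum in [0.2, 2.0] s with normalized value ≥ 0.2 (cadences 30–300 spm;
below the value floor the window is treated as non-periodic and the
estimate is null).

## Biomarkers

**Quantity.** Steps per day sums detected step events inside each local
calendar day, so a bout straddling midnight contributes each step to the
day it actually occurred in. Longest walk is the maximal bout duration.
Arm-mode proportions divide per-mode walking duration by total walking
duration (they sum to 100%). The step–walk gradient fits
log(number of walks) on log(steps per walk) — one point per distinct step
count when there are few, otherwise per occupied log-spaced bin using the
bin's mean log step count (bin centres alias badly against discrete step
counts) — and reports β₁ × 100; fewer than three occupied bins give null.
Cumulative exposure X_i and the short-walk percentages are exact
evaluations of their definitions. The short-walk thresholds default to
8 s and 60 s; the method's text and its summary table disagree between
7 s and 8 s for the first threshold, so both are supported and the table's
8 s is the default (the naming users will encounter).

**Speed.** A Gaussian-kernel SVR (`gamma = 1/7` on standardized
predictors, C = 10, ε = 0.01 on a standardized target) maps the seven
canonical features of each arm-swing walking window to speed; 10-fold
cross-validated MAPE accompanies every fit (subject-partitioned folds when
ids are given). Daily speed biomarkers are the median, 95th percentile and
IQR of per-window predictions, with linear interpolation; speed estimation
is restricted to arm-swing windows, matching the biomarker's definition
and the model's arm-mode-sensitive features.

**Quality.** Steps are regrouped into 8-step episodes, truncating
remainders (18 steps → two episodes). An episode records 8 step-event
times; its duration spans eight step periods, taken as 8 × the mean of the
7 observed inter-step intervals, so cadence = 480/duration is exact for
evenly spaced steps and the episode's step-time SD is the SD of those 7
intervals. Daily step-time variability is the mode e^(μ−σ²) of a
log-normal model over the day's episode SDs (μ, σ the maximum-likelihood
mean and SD of the logs; non-positive SDs dropped; fewer than 10 remaining
gives null) — the mode is the distribution's most probable value and is
robust to the long right tail of occasional irregular walks. The 8-step
harmonic ratio takes the FFT of the static-removed norm over exactly the
episode span, where the step frequency is the 8th spectral harmonic:
stabilising amplitudes at harmonics {8, 16, …, 80}, destabilising at the
odd stride harmonics {4, 12, …, 76}, hr = Σstab/Σdestab, capped at 10
when the destabilising sum vanishes (a perfectly periodic signal). The
exact bin grouping of the original reference implementation is not
published; this grouping follows the standard harmonic-ratio literature
and is exposed as configuration. Step and stride regularity are the
unbiased normalized autocorrelation at the local peaks nearest one and two
mean step times (±40% search bands), reported ×100 at the panel level.

**Aggregation.** A day is valid with ≥ 22.8 h of wear (95% of the day —
exact 24-h wear is unattainable once exclusions are applied; threshold
configurable) and at least one walking bout. Week aggregates are means
over valid days (the original report does not say mean or median; mean is
the package's choice), and a subject's panel is valid with at least five
valid days.

## Cohort statistics

ICC(2,k) is computed from the two-way mean squares (subjects × days):
ICC = (MSR − MSE)/(MSR + (MSC − MSE)/n), with variance components
(MSR−MSE)/k, (MSC−MSE)/n and MSE reported alongside. Missing cells are
allowed up to 20%, handled by listwise-complete fit (subjects with any
missing day are dropped from the decomposition). Kruskal–Wallis uses the
tie-corrected statistic; Dunn pairwise z-tests use pooled mid-ranks with
the standard tie term and Holm adjustment (the original reports Dunn
without naming the adjustment; all its pairwise contrasts were < 0.001,
insensitive to the choice). ANOVA pairs with Tukey HSD; the chi-square
test is Pearson's without continuity correction, with all-positive
expected counts required. MAPE is mean(|est − truth|/truth) × 100.

## The simulator

`simulate` exists because the cohorts this method was built on are
access-restricted: it generates the study's signal classes with full
ground truth rather than imitating any particular dataset.

The wrist model per walking segment: a 1 g gravity vector in a
mode-specific orientation; a half-sine impact transient per step along the
vertical (amplitude 0.25 g by default, alternating ±asymmetry for
stride-level structure); for arm-swing walking, a 0.3 g sinusoid at *half*
the step frequency on a horizontal axis — each arm swings once per stride,
which is exactly what makes the norm's first autocorrelation peak a step
and its second a stride; carry modes suppress the swing and instead couple
a small step-frequency rocking component into two axes, separating their
correlation signatures; running raises amplitude and cadence; unstructured
arm activity is band-limited (0.3–1.5 Hz) noise on all axes; vehicle
travel is sub-0.5 Hz vibration on a 1 g baseline; non-wear is constant
with 3 mg microjitter (safely inside the 13 mg rule it must trigger);
sleep is a stable posture with a ≪ 5°/5 s drift but full physiological
noise (so it must be caught by the sleep rule, not the non-wear rule).
Step times sit on the cadence grid with independent Gaussian jitter of 2%
of a step period, so a segment realizes exactly round(duration·cadence/60)
steps. Segments concatenate with a 1-s crossfade from the previous
posture. Everything is deterministic given the master seed.

True walking speed follows a fixed smooth map,
speed = 0.006·cadence [spm] + 1.0·impact amplitude [g] + 0.30·height [m] − 0.10,
with coefficients chosen so that everyday cadences, amplitudes and
statures land in the 1.0–1.6 m/s range; specifying a segment speed inverts
the map for the impact amplitude. This gives the speed regression a
recoverable target through exactly its seven features. The default
mixed-day schedule draws per-subject latent traits (cadence 95–125 spm,
speed 1.1–1.6 m/s, stature 1.55–1.90 m, noise 15–35 mg) so windows within
a subject are correlated — the regime subject-partitioned CV exists for.

`simulate_cohort` operates at panel level (biomarker values, not raw
signal): value = base + group shift + subject effect + day effect +
residual, which makes the analytic ICC(2,k) of the generating model,
σ²_b/(σ²_b + (σ²_day + σ²_w)/k), available as ground truth. Raw-signal
cohorts at 100 Hz × days × subjects are far beyond desk scale and would
add nothing to what `simulate_day` already validates.

**What passing tests do and do not show.** The simulator's gait is far
cleaner than real wrist data: near-sinusoidal band-channel waveforms,
stationary cadence within a segment, no soft-tissue artifacts, no device
reorientation on the wrist, discrete rather than gradual activity
transitions, and timing jitter that the 0.25–2.5 Hz filter partially
absorbs (detected step-time variability is therefore lower than the
generated jitter). Passing accuracy targets on it demonstrates that the
algorithms are implemented correctly and are calibrated — that the
detector counts what the waveform contains, the classifier separates what
the features encode, the estimators converge to their closed forms — not
that the same error levels would be achieved on free-living recordings.

## Problem sizes

The test suite and the acceptance script run everything at desk scale as
the package's own working sizes: 124-s walks across 30 cadence×mode
conditions for step accuracy; 20 subjects × ~25-minute mixed days
(~3,700 windows) for classification; n = 5000 per cell of a 3×3 (μ, σ)
grid for log-normal mode recovery; 500 subjects × 7 days for ICC
recovery; 25 walks (~775 windows) for the speed regression; 500 null
replicates for test calibration.
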