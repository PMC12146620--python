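# Methods

This note records the models, conventions and numerical choices behind
`gbsig`, and what the synthetic-data generators do and do not emulate.

## Conventions

Time is measured in seconds from injection start (t = 0); all windows are
half-open `[a, b)`; negative times are pre-injection. ΔF/F = (Ft − F0)/F0
is kept as a dimensionless fraction internally (the 2 %-ΔF/F oscillation
threshold in `RunConfig` is therefore divided by 100 at the point of use).
F0 is the mean over the modality's baseline window: 50 s pre-injection for
wide-field and two-photon, 30 s for photometry and nerve recordings. A
degenerate baseline (F0 ≤ 0, or zero variance where an SD is needed) is an
error naming the offending ROI/cell, never silently patched.

Widths: a peak's `width` is the **full** width at half prominence
(prominence = excursion above the local baseline; for averaged pulses,
above the baseline-window mean). HWHM is half of that full width, so a
Gaussian pulse of parameter σ has HWHM = σ·√(2 ln 2) ≈ 1.177 σ. Crossing
times are linearly interpolated, making both measures accurate to well
under one sample period on smooth pulses.

## Wide-field pipeline

Binning is block-averaging (any remainder rows/columns at the bottom/right
are cropped). The low-pass filter is a 4th-order Butterworth applied
forward–backward (`sosfiltfilt`): zero phase, unit DC gain; only the cutoff
(1 Hz) is an analysis constant, the realization is a package choice.

Peak detection keeps strict local maxima with ΔF/F > 0 ("exceeding the
baseline value" read as: above the baseline mean after ΔF/F conversion)
and topographic prominence ≥ 0.5 × the trace's baseline-window SD — a
noise floor the analysis needs but that the procedure's verbal description
leaves open; it is exposed as `prominence_sd_mult`.

Peak ratios pair each target-region peak with a reference-region peak by a
one-to-one assignment that maximizes the number of pairs with
|Δt| ≤ tolerance and, among those, minimizes total |Δt| (Hungarian
algorithm; exact ties nudged toward the earlier reference peak). The
tolerance defaults to half the median reference inter-peak interval, so
for quasi-periodic slow waves every instant lies within tolerance of some
reference peak. The activation level uses the earliest matched wave inside
[3, 8) s; if no wave falls there the result is flagged invalid and NaN —
a later wave is never substituted.

Properties the tests verify: the reference region's activation level is
identically 1; the whole statistic is invariant to a global multiplicative
gain of the movie; on null movies (no evoked term) the frontal activation
level averages to 1 within Monte-Carlo error.

## Two-photon pipeline

The ±0.5 SD criterion is instantaneous — a single supra-threshold sample
inside [15, 38) s suffices (`min_dwell` = 0 by default; a dwell
requirement can be configured). The 15–38 s window is a fixed analysis
constant (the typical duration of the population astrocyte response), not
recomputed from data. Cells crossing both thresholds are assigned by the
larger absolute z-excursion, ties to Increase; the serial verbal
definition leaves this case open, and the choice makes the partition
exhaustive and exclusive. Classification is scale-equivariant (labels
depend only on z-scores).

Class-average waveform metrics take the mean trace of a class, then:
onset = first post-injection crossing of the mean trace's baseline mean
± 0.5 SD (sign per class, interpolated, clamped at t = 0), peak time =
argmax (Increase) or argmin (Decrease), HWHM as above with the sign
flipped for Decrease.

## Photometry pipeline

Ratiometric (FRET) input uses signal = yellow/cyan before ΔF/F — the ratio
that rises with Ca²⁺; the recorded 405 nm isosbestic channel is accepted in
files but unused (no correction step is part of the procedure). kHz-rate
traces are analyzed at native rate; windows are in seconds, so no
resampling is needed.

The cohort analysis window is the [min, max] over animals of all
post-injection times where an animal's ΔF/F exceeds its own baseline mean
+ 3 SD (mirror with − 3 SD for downregulation). Animals with no crossing
are excluded and reported; no animal crossing at all is an error. This
min/max rule is monotone — adding an animal can only widen the window —
and with a single supra-threshold epoch per animal, "first/last crossing"
and "full support" coincide. "Top 30 %" means samples at or above the 70th
percentile (linear-interpolation quantile, ties included), computed over
samples, not per-peak values.

One estimator caveat the tests respect: the in-window **median** is an
unbiased location estimate only where the in-window signal distribution is
locally symmetric. When the analysis window extends deep into a pulse's
decay tail (e.g., because one animal's noise crosses + 3 SD late), the
median sits on a sparse, skewed part of the sample distribution and
acquires a small noise-dependent bias — a property of the estimator, not
of the implementation. The Monte-Carlo recovery tests therefore pin the
analysis window to the pulse's elevated phase; the window-derivation rule
is tested separately on noiseless traces where it equals the true
supra-threshold support.

## Nerve-recording pipeline

High-pass: 4th-order zero-phase Butterworth at 50 Hz. Normalization maps
the spontaneous mean to 0 and the spontaneous maximum to 1, making the
whole chain invariant to positive affine gain of the raw signal. The
counting thresholds — median + 2 SD (count) and median + 5 SD (exclude as
noise) — are computed once from the normalized spontaneous segment and
applied to the entire record (fixed, not rolling). Exclusion drops whole
peaks, never clips them. A refractory distance (default 1 ms) prevents one
spike's ripples from double-counting; within that distance the larger peak
wins. Per-second bins are aligned to integer seconds relative to injection
start; the baseline rate is the mean count over the 30 s pre-injection
bins, the post rate over [2, 4) s, and their ratio is the normalized peak
frequency (undefined when the baseline rate is 0).

## Synthetic-data generators

All generators are pure functions of (parameters, seed). Defaults are the
study conditions the pipelines assume; sizes were chosen so the full test
suite and the verification script run in minutes on one core.

**Wide-field** (130 s @ 10 Hz, injection at 60 s, 64×64): a global 0.2 Hz
sinusoid with random-walk phase jitter (0.05 rad/frame) stands in for the
anesthesia Up/Down oscillation — a deliberate simplification of the
irregular real rhythm. Regional amplitude scales (frontal 0.030 …
occipital 0.050 ΔF/F) reproduce the higher occipital amplitudes; an
optional frontal-only Gaussian transient (default 0.1 ΔF/F, peak 4.5 s
post-injection, σ = 0.8 s) is the evoked wave; i.i.d. Gaussian pixel noise
(sd 0.5 on a base intensity of 100) averages out over ROI masks.

**Photometry** (150 s, injection at 60 s): neurons are a single
alpha-function pulse (amplitude 0.3 ΔF/F, onset 2 s, τ = 8 s; an optional
sustained plateau parameter exists for late-phase studies and defaults to
0); astrocytes are dual-channel ratiometric at 1 kHz with a rise pulse
plus a negative undershoot starting 40 s post-injection (τ = 15 s).
Additive linear drift (2·10⁻⁵ ΔF/F per s) and Gaussian noise
(sd 0.01 ΔF/F; low-passed at 2 Hz for kHz-rate records so the noise
correlation time matches slow indicator dynamics).

**Two-photon** (150 s @ 10 Hz): cells drawn from the (0.2, 0.5, 0.3)
Increase/Decrease/Nonresponse mixture. Increase cells get an alpha pulse
(amp 0.2, onset 18 s post-injection, τ = 7 s, peaking at 25 s inside the
classification window); Decrease cells a mirrored negative pulse whose
onset lags by 9 s. Every cell carries two zero-mean spontaneous
fluctuation bursts (one 4 s sine cycle, amp 0.08) at random pre-injection
times: these dominate the baseline SD (≈0.023 ΔF/F) while leaving the
baseline mean at the resting level, and the fast noise default
(0.003 ΔF/F) is kept small against that SD. This structure is what the
±0.5 SD instantaneous rule requires — if in-window fluctuations were
comparable to the baseline SD, every cell would cross a half-SD line
somewhere in a 23 s window. Real recordings earn this margin through slow
indicator kinetics and event-sparse quiescent periods; the generator
encodes it directly, which also means the generator does **not** emulate
spontaneous events continuing after injection. Passing tests show the
classifier implements the rule faithfully, not that the rule is robust to
arbitrary post-injection background activity.

**Nerve** (45 s @ 20 kHz, injection at 35 s): inhomogeneous-Poisson spike
times (baseline 15/s; × multiplier inside [0, 6) s post-injection), each
adding a 0.8 ms biphasic (one sine cycle) waveform with lognormal
amplitude jitter (σ = 0.1). Background noise is **uniform** (bounded,
sd ≈ 0.29 under unit spike amplitude): a platykurtic background is the one
way a fixed median + 2 SD line can sit above the noise ceiling so that
counted peaks are unit spikes — with Gaussian background of the same SD
the 2-SD line is crossed by noise maxima at kHz rates and threshold
counting cannot recover rates. The 50 Hz high-pass barely perturbs the
bound (it subtracts a low-frequency component with ≈7 % of the noise SD).
Artifacts are sparse large Gaussian-shaped blips (0.2/s, amplitude 4×
spike amplitude) that land above the + 5 SD exclusion line. Amplitude
jitter puts a stationary fraction of unit peaks outside the (2 SD, 5 SD]
band; because that fraction is the same pre- and post-injection it cancels
in the normalized peak frequency, and only spike-waveform collisions
(≈2–4 % at these rates) bias the ratio — within Monte-Carlo error in the
calibration tests.

## Statistics

Implemented over `scipy.stats` (t-tests, Wilcoxon, ANOVA, `tukey_hsd`,
which applies the Tukey–Kramer unequal-n standard error). All tests are
two-sided. Wilcoxon uses the exact null for n ≤ 25 when differences are
nonzero and untied, otherwise the normal approximation with continuity
correction. Summary tables report mean ± SD and also SEM, since published
"±" values are ambiguous between the two. The test suite cross-checks all
six methods against R (`t.test`, `wilcox.test`, `aov` + `TukeyHSD`) to
1 × 10⁻⁶ on fixed fixtures, covering both Wilcoxon branches. With two
groups, Tukey–Kramer reproduces the pooled t-test's p-value (q = t·√2);
this identity is asserted in the tests.

## Known limitations

* The generators emulate the statistical structure each analysis assumes,
  not biophysics: no hemodynamic contamination, photobleaching, motion,
  cardiac/respiratory artifacts, or indicator nonlinearity.
* The wide-field slow wave is quasi-periodic by construction; peak-ratio
  matching tolerance (half the median reference inter-peak interval) has
  only been exercised on such rhythms.
* The nerve generator's bounded background is a design device (see above);
  real recordings with heavy-tailed background would push noise peaks into
  the counting band and bias rates upward — the pipeline reports raw
  counts, it does not denoise.
* ImageJ ROI support covers polygon/freehand outlines only (the subset
  hand-drawn region work needs), with simple (non-self-intersecting)
  polygons assumed in rasterization.
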