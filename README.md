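# gbsig

Analysis pipelines for gut→brain signaling experiments: how an intragastric
(IG) glucose infusion, sensed in the intestine and relayed through the vagus
nerve, shows up in cortical and afferent recordings. The package implements
the four recording-modality analyses used in such studies, the group
statistics applied to their per-animal outputs, and seeded synthetic-data
generators that emulate every modality so the whole chain is testable
without any raw-data download.

**Who it is for.** Systems-neuroscience labs quantifying visceral→cortical
signaling from wide-field Ca²⁺ movies, fiber-photometry traces, two-photon
per-cell recordings, or whole-nerve cuff-electrode recordings, with t = 0
defined at infusion start and all analysis windows in seconds relative to
it (half-open `[a, b)`; negative = pre-injection).

## The analyses

**Wide-field cortical activation.** Movies (512×512 @ 10 Hz) are binned to
64×64; per-ROI ΔF/F = (Ft − F0)/F0 with F0 the mean over the 50 s before
injection; traces are low-passed at 1 Hz (zero-phase Butterworth) and Ca²⁺
oscillation peaks above baseline are detected. Each region's peak amplitudes
are divided by the time-matched peak of a Reference (auditory) ROI, giving
peak ratios; the **activation level** is the earliest ratio in [3, 8) s
post-injection divided by the mean spontaneous ratio over [−50, 0) s.
Oscillations exceeding 2 % ΔF/F contribute widths (full width at half
prominence) for the spontaneous vs late [10, 60) s comparison.

**Fiber photometry.** Per-animal ΔF/F against a 30 s baseline (yellow/cyan
ratio first for ratiometric FRET sensors). Up-/down-regulation crossing
times at baseline mean ± 3 SD define, via the cohort-wide min/max, a common
analysis window. Neuronal amplitude = median(in-window) − median(baseline);
astrocytic amplitude = mean of the top 30 % of in-window samples − baseline
mean; the downregulation metric mirrors it with the bottom 30 % of the
baseline. Average waveforms yield peak onset and HWHM; a paired
[−50, 0) vs [30, 80) s comparison tests sustained late elevation.

**Two-photon classification.** Each cell is labeled **Increase** if any
ΔF/F sample within 15–38 s post-injection exceeds its baseline mean
+ 0.5 SD, **Decrease** below − 0.5 SD, otherwise **Nonresponse**; per-animal
label proportions and class-average waveform metrics follow.

**Vagus-nerve spike rate.** Recordings are 50 Hz high-passed, normalized as
x′ = (x − μ_sp)/(max_sp − μ_sp) over the 30 s spontaneous state, and peaks
with amplitude in (median + 2 SD, median + 5 SD] of the normalized data are
counted per second (larger peaks are excluded as noise artifacts). The
**normalized peak frequency** is the [2, 4) s post-injection rate over the
spontaneous rate.

**Statistics.** Pooled/Welch/paired t, Wilcoxon signed-rank (exact for
n ≤ 25 without ties), one-way ANOVA and Tukey–Kramer post hoc tests
(studentized-range with unequal-n correction), tidy mean ± SD summary
tables, and the two-bottle preference ratio
100 × sugar consumption / total fluid consumption.

## Worked example

```sh
python examples/widefield_activation.py
```

```
   region  activation_level  spontaneous_mean_width_s  late_mean_width_s
  Frontal             2.350                     2.521              2.523
   Somato             0.978                     2.516              2.523
Reference             1.000                     2.522              2.532
      RSC             0.986                     2.518              2.527
   Visual             0.982                     2.519              2.527
```

The synthetic movie carries a frontal-only evoked transient (0.1 ΔF/F) on
top of the global slow oscillation: only the Frontal region's activation
level rises above 1 (here 2.35), while the other regions stay at ≈1 and the
Reference region is exactly 1 by construction. Widths are the full widths
at half prominence of the detected slow waves, in seconds.

The other examples (`photometry_response.py`, `twophoton_classification.py`,
`vagus_spike_rate.py`, `group_statistics.py`) exercise the remaining
pipelines the same way. Equivalent shell entry points:

```sh
gbsig simulate widefield --seed 0 --out sim/
gbsig widefield sim/movie.tif sim/rois.zip --t-injection 60 --out results/
gbsig stats table.csv --test tukey_kramer --out results/
```

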