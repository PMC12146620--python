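"""Vagus-nerve extracellular recording analysis.

Chain: zero-phase 50 Hz high-pass → normalization against the spontaneous
(30 s pre-injection) mean and maximum → peak counting in the
(median + 2 SD, median + 5 SD] band of the normalized data (median/SD from
the normalized spontaneous segment; peaks above +5 SD are removed as noise
artifacts) → per-second counts → baseline rate (30 s pre), post rate
([2, 4) s) and their ratio, the normalized peak frequency.

The whole chain is invariant to a positive affine gain of the raw signal:
the high-pass removes the offset and the normalization removes the gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._signal import highpass_zero_phase, window_mask
from .io import Recording


@dataclass
class SpikeRateResult:
    """Per-second nerve peak counts and the pre/post rate comparison."""

    per_second: pd.Series          # index: bin start (s rel. injection)
    baseline_rate: float           # mean peaks/s over 30 s pre
    post_rate: float               # mean peaks/s over [2, 4) s
    normalized_frequency: float    # post_rate / baseline_rate
    excluded_artifacts: int
    n_peaks: int


@dataclass
class ExcludedPeak:
    time: float       # s relative to injection
    amplitude: float  # normalized units


def highpass(rec: Recording, cutoff: float = 50.0) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass of the raw recording."""
    if rec.samples.ndim != 1:
        raise ValueError("ephys recordings are single-channel")
    filtered = highpass_zero_phase(rec.samples, cutoff, rec.sampling_rate)
    return Recording(samples=filtered, sampling_rate=rec.sampling_rate,
                     t_injection=rec.t_injection,
                     injection_duration=rec.injection_duration,
                     modality=rec.modality)


def normalize_spontaneous(rec: Recording, baseline: float = 30.0
                          ) -> Recording:
    """x′ = (x − μ_sp)/(max_sp − μ_sp): the spontaneous mean maps to 0 and
    the spontaneous maximum to 1."""
    times = rec.times
    bmask = window_mask(times, -baseline, 0.0)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    x = rec.samples
    mu = float(x[bmask].mean())
    mx = float(x[bmask].max())
    if mx <= mu:
        raise ValueError("degenerate spontaneous segment: max <= mean")
    return Recording(samples=(x - mu) / (mx - mu),
                     sampling_rate=rec.sampling_rate,
                     t_injection=rec.t_injection,
                     injection_duration=rec.injection_duration,
                     modality=rec.modality)


def _threshold_stats(rec: Recording, baseline: float
                     ) -> tuple[float, float]:
    bmask = window_mask(rec.times, -baseline, 0.0)
    seg = rec.samples[bmask]
    med = float(np.median(seg))
    sd = float(seg.std(ddof=0))
    if sd == 0:
        raise ValueError("zero-variance spontaneous segment")
    return med, sd


def _band_peaks(rec: Recording, baseline: float, peak_sd: float,
                noise_sd: float, refractory: float
                ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Local maxima above the counting line across the whole record, split
    into counted (≤ noise line) and excluded (> noise line) indices."""
    med, sd = _threshold_stats(rec, baseline)
    lower = med + peak_sd * sd
    upper = med + noise_sd * sd
    distance = max(int(round(refractory * rec.sampling_rate)), 1)
    # strict > on the counting line
    idx, _ = sps.find_peaks(rec.samples,
                            height=np.nextafter(lower, np.inf),
                            distance=distance)
    amp = rec.samples[idx]
    counted = idx[amp <= upper]
    excluded = idx[amp > upper]
    return counted, excluded, lower, upper


def count_peaks(rec: Recording, baseline: float = 30.0,
                peak_sd: float = 2.0, noise_sd: float = 5.0,
                refractory: float = 1e-3,
                post_window: tuple[float, float] = (2.0, 4.0)
                ) -> SpikeRateResult:
    """Count nerve peaks and assemble the pre/post rate comparison.

    Peaks are local maxima of the normalized record with amplitude in
    (median + ``peak_sd``·SD, median + ``noise_sd``·SD], separated by at
    least ``refractory`` seconds; the median and SD come from the
    normalized spontaneous segment. Counts are binned into 1 s bins whose
    edges fall on integer seconds relative to injection start.
    """
    counted, excluded, _, _ = _band_peaks(rec, baseline, peak_sd, noise_sd,
                                          refractory)
    times = rec.times
    peak_t = times[counted]
    t0 = np.floor(times[0])
    t1 = np.ceil(times[-1])
    edges = np.arange(t0, t1 + 1.0)
    counts, _ = np.histogram(peak_t, bins=edges)
    per_second = pd.Series(counts, index=edges[:-1], name="peaks_per_s")
    bl = per_second[(per_second.index >= -baseline) & (per_second.index < 0)]
    post = per_second[(per_second.index >= post_window[0])
                      & (per_second.index < post_window[1])]
    baseline_rate = float(bl.mean()) if len(bl) else np.nan
    post_rate = float(post.mean()) if len(post) else np.nan
    norm = post_rate / baseline_rate if baseline_rate > 0 else np.nan
    return SpikeRateResult(per_second=per_second,
                           baseline_rate=baseline_rate,
                           post_rate=post_rate,
                           normalized_frequency=norm,
                           excluded_artifacts=int(len(excluded)),
                           n_peaks=int(len(counted)))


def artifact_exclusion_report(rec: Recording, baseline: float = 30.0,
                              peak_sd: float = 2.0, noise_sd: float = 5.0,
                              refractory: float = 1e-3
                              ) -> List[ExcludedPeak]:
    """Every local maximum above the median + ``noise_sd``·SD line, with
    its time (s relative to injection) and normalized amplitude."""
    _, excluded, _, _ = _band_peaks(rec, baseline, peak_sd, noise_sd,
                                    refractory)
    times = rec.times
    return [ExcludedPeak(time=float(times[i]), amplitude=float(rec.samples[i]))
            for i in excluded]


def analyze_recording(rec: Recording, hpf_cutoff: float = 50.0,
                      baseline: float = 30.0, peak_sd: float = 2.0,
                      noise_sd: float = 5.0, refractory: float = 1e-3,
                      post_window: tuple[float, float] = (2.0, 4.0)
                      ) -> SpikeRateResult:
    """Full chain: high-pass → spontaneous normalization → peak counting."""
    filtered = highpass(rec, hpf_cutoff)
    normalized = normalize_spontaneous(filtered, baseline)
    return count_peaks(normalized, baseline, peak_sd, noise_sd,
                       refractory, post_window)
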