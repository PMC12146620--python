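"""Fiber-photometry population-level metrics.

Per-animal ΔF/F against a 30 s pre-injection baseline (for ratiometric
recordings, the yellow/cyan channel ratio is formed first), ±3 SD
up-/down-regulation crossing times, a cohort analysis window spanning the
min–max of all animals' crossing times, median-based (neuron) and
top-/bottom-30 % (astrocyte) amplitude metrics, average-waveform onset and
HWHM, and the within-animal late-phase comparison of [−50, 0) vs [30, 80) s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from ._signal import WaveformMetrics, pulse_metrics, window_mask
from .io import Recording
from .widefield import DffTrace


def dff(rec: Recording, baseline: float = 30.0,
        numerator: str = "yellow", denominator: str = "cyan") -> DffTrace:
    """ΔF/F (or ΔR/R for dual-channel ratiometric input) of a recording.

    For multi-channel recordings the signal is the ``numerator`` channel
    divided by the ``denominator`` channel sample-wise; F0 is the mean over
    the ``baseline`` seconds preceding injection.
    """
    if rec.samples.ndim == 2:
        num = rec.channel(numerator)
        den = rec.channel(denominator)
        if np.any(den == 0):
            raise ValueError("ratiometric denominator contains zeros")
        signal = num / den
    else:
        signal = rec.samples
    times = rec.times
    bwin = (-baseline, 0.0)
    bmask = window_mask(times, *bwin)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    f0 = float(signal[bmask].mean())
    if f0 <= 0:
        raise ValueError(f"degenerate baseline F0={f0}")
    return DffTrace(values=(signal - f0) / f0, times=times,
                    baseline_window=bwin, f0=f0)


@dataclass
class CohortWindow:
    """Cohort analysis window from per-animal threshold-crossing times."""

    window: tuple[float, float]
    per_animal: List[tuple[float, float]]
    excluded: List[int] = field(default_factory=list)


def _crossing_times(trace: DffTrace, sd_mult: float, direction: int
                    ) -> np.ndarray:
    """Post-injection times where the trace exceeds baseline mean
    ± ``sd_mult``·SD (direction +1 above, −1 below)."""
    bmask = window_mask(trace.times, *trace.baseline_window)
    mu = trace.values[bmask].mean()
    sd = trace.values[bmask].std(ddof=0)
    post = trace.times >= 0.0
    if direction > 0:
        hit = trace.values > mu + sd_mult * sd
    else:
        hit = trace.values < mu - sd_mult * sd
    return trace.times[post & hit]


def upregulation_window(traces: Sequence[DffTrace], sd_mult: float = 3.0
                        ) -> CohortWindow:
    """Cohort analysis window for upregulation.

    Each animal contributes the times at which its post-injection ΔF/F
    exceeds its own baseline mean + ``sd_mult``·SD; the cohort window spans
    the minimum to the maximum of all contributed times. Animals with no
    crossing are excluded and reported. Adding an animal can only widen or
    preserve the window.
    """
    return _cohort_window(traces, sd_mult, +1)


def downregulation_window(traces: Sequence[DffTrace], sd_mult: float = 3.0
                          ) -> CohortWindow:
    """Mirror of :func:`upregulation_window` for sub-threshold times."""
    return _cohort_window(traces, sd_mult, -1)


def _cohort_window(traces: Sequence[DffTrace], sd_mult: float,
                   direction: int) -> CohortWindow:
    per_animal: List[tuple[float, float]] = []
    excluded: List[int] = []
    lo, hi = np.inf, -np.inf
    for i, tr in enumerate(traces):
        ct = _crossing_times(tr, sd_mult, direction)
        if len(ct) == 0:
            excluded.append(i)
            continue
        a, b = float(ct.min()), float(ct.max())
        per_animal.append((a, b))
        lo, hi = min(lo, a), max(hi, b)
    if not per_animal:
        raise ValueError("no animal crossed the threshold; "
                         "cohort window undefined")
    return CohortWindow(window=(lo, hi), per_animal=per_animal,
                        excluded=excluded)


def neuron_amplitude(trace: DffTrace, window: tuple[float, float]) -> float:
    """Upregulation change of the neuronal Ca²⁺ level: in-window median
    ΔF/F minus baseline median ΔF/F."""
    wmask = window_mask(trace.times, *window)
    if not wmask.any():
        raise ValueError("analysis window contains no samples")
    bmask = window_mask(trace.times, *trace.baseline_window)
    return float(np.median(trace.values[wmask])
                 - np.median(trace.values[bmask]))


def top_fraction_mean(x: np.ndarray, fraction: float = 0.3) -> float:
    """Mean of the samples at or above the (1 − fraction) quantile
    (linear-interpolation threshold; ties included)."""
    x = np.asarray(x, dtype=float)
    thr = np.quantile(x, 1.0 - fraction)
    return float(x[x >= thr].mean())


def bottom_fraction_mean(x: np.ndarray, fraction: float = 0.3) -> float:
    """Mean of the samples at or below the ``fraction`` quantile."""
    x = np.asarray(x, dtype=float)
    thr = np.quantile(x, fraction)
    return float(x[x <= thr].mean())


def astro_amplitude(trace: DffTrace, window: tuple[float, float]) -> float:
    """Upregulation change of the astrocytic Ca²⁺ level: mean of the top
    30 % of in-window ΔF/F samples minus the baseline mean."""
    wmask = window_mask(trace.times, *window)
    if wmask.sum() < 4:
        raise ValueError("analysis window needs at least 4 samples")
    bmask = window_mask(trace.times, *trace.baseline_window)
    return float(top_fraction_mean(trace.values[wmask])
                 - trace.values[bmask].mean())


def downregulation_metric(trace: DffTrace, window: tuple[float, float]
                          ) -> float:
    """Downregulation change: in-window mean ΔF/F minus the mean of the
    bottom 30 % of baseline samples (typically negative)."""
    wmask = window_mask(trace.times, *window)
    if not wmask.any():
        raise ValueError("analysis window contains no samples")
    bmask = window_mask(trace.times, *trace.baseline_window)
    return float(trace.values[wmask].mean()
                 - bottom_fraction_mean(trace.values[bmask]))


def waveform_metrics(trace: DffTrace, polarity: int = +1,
                     sd_mult: float = 0.5,
                     search_window: Optional[tuple[float, float]] = None
                     ) -> WaveformMetrics:
    """Onset, peak time and HWHM of an (averaged) photometry trace."""
    return pulse_metrics(trace.values, trace.times, trace.baseline_window,
                         polarity=polarity, sd_mult=sd_mult,
                         search_window=search_window)


def late_phase_comparison(trace: DffTrace,
                          spontaneous_window: tuple[float, float] = (-50.0, 0.0),
                          late_window: tuple[float, float] = (30.0, 80.0)
                          ) -> tuple[float, float]:
    """Within-animal means over the spontaneous and late windows,
    to be fed to a paired group comparison across animals."""
    sp = window_mask(trace.times, *spontaneous_window)
    lt = window_mask(trace.times, *late_window)
    if not sp.any() or not lt.any():
        raise ValueError("record does not cover both comparison windows")
    return float(trace.values[sp].mean()), float(trace.values[lt].mean())
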