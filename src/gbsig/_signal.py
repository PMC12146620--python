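"""Shared signal primitives: zero-phase filters, window masks, peak widths,
and pulse waveform metrics (onset / peak time / HWHM).

Conventions: time is seconds relative to injection start; windows are
half-open ``[a, b)``; widths are measured at half of peak prominence, where
a pulse's prominence is its excursion from the baseline-window mean. HWHM is
half of the full width at half prominence, so a Gaussian pulse of width
parameter σ has HWHM = σ·sqrt(2 ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps


def window_mask(times: np.ndarray, a: float, b: float) -> np.ndarray:
    """Boolean mask for the half-open interval [a, b) on a time axis."""
    return (times >= a) & (times < b)


def _butter_sos(cutoff: float, fs: float, btype: str, order: int = 4):
    nyq = fs / 2.0
    if cutoff >= nyq:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyq} Hz"
        )
    return sps.butter(order, cutoff, btype=btype, fs=fs, output="sos")


def lowpass_zero_phase(x: np.ndarray, cutoff: float, fs: float,
                       order: int = 4) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth low-pass; unit DC gain."""
    sos = _butter_sos(cutoff, fs, "lowpass", order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def highpass_zero_phase(x: np.ndarray, cutoff: float, fs: float,
                        order: int = 4) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth high-pass; DC removed."""
    sos = _butter_sos(cutoff, fs, "highpass", order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def interp_crossing(t0: float, t1: float, v0: float, v1: float,
                    level: float) -> float:
    """Linear-interpolated time at which a segment crosses ``level``."""
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def width_at_level(values: np.ndarray, times: np.ndarray, peak_idx: int,
                   level: float) -> tuple[Optional[float], Optional[float]]:
    """Interpolated crossing times of ``level`` nearest to a peak.

    Returns ``(t_left, t_right)``; a side is ``None`` when the trace never
    falls below the level before the record edge on that side.
    """
    t_left = t_right = None
    for i in range(peak_idx, 0, -1):
        if values[i - 1] < level <= values[i]:
            t_left = interp_crossing(times[i - 1], times[i],
                                     values[i - 1], values[i], level)
            break
    for i in range(peak_idx, len(values) - 1):
        if values[i + 1] < level <= values[i]:
            t_right = interp_crossing(times[i], times[i + 1],
                                      values[i], values[i + 1], level)
            break
    return t_left, t_right


@dataclass
class WaveformMetrics:
    """Onset, peak time and half width at half maximum of a pulse.

    ``onset`` is the first post-injection threshold crossing, ``peak_time``
    the extremum time, and ``hwhm`` half of the full width measured at half
    of the pulse's prominence over the baseline mean. All in seconds.
    """

    onset: Optional[float]
    peak_time: Optional[float]
    hwhm: Optional[float]
    peak_value: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.onset is not None and self.peak_time is not None
                and self.onset > self.peak_time):
            raise ValueError("onset must not exceed peak time")


def pulse_metrics(values: np.ndarray, times: np.ndarray,
                  baseline_window: tuple[float, float],
                  polarity: int = +1, sd_mult: float = 0.5,
                  search_window: Optional[tuple[float, float]] = None,
                  ) -> WaveformMetrics:
    """Waveform metrics of a single evoked pulse in an averaged trace.

    The trace is sign-flipped for negative-going (``polarity=-1``) pulses.
    Onset is the first crossing of baseline mean + ``sd_mult``·SD at or
    after t = 0 (linearly interpolated); peak time is the argmax within
    ``search_window`` (default: everything from t = 0 on); HWHM is half the
    full width at half prominence, with crossing times interpolated.
    """
    values = np.asarray(values, dtype=float) * polarity
    times = np.asarray(times, dtype=float)
    bmask = window_mask(times, *baseline_window)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    mu = values[bmask].mean()
    sd = values[bmask].std(ddof=0)

    if search_window is None:
        search_window = (0.0, float(times[-1]) + 1e-12)
    smask = window_mask(times, *search_window)
    if not smask.any():
        raise ValueError("search window contains no samples")
    idx = np.flatnonzero(smask)
    peak_idx = idx[np.argmax(values[idx])]
    peak_time = float(times[peak_idx])
    peak_value = float(values[peak_idx]) * polarity

    thr = mu + sd_mult * sd
    onset = None
    post = np.flatnonzero(times >= 0.0)
    for i in post:
        if values[i] > thr:
            if i > 0 and values[i - 1] <= thr:
                # crossing interpolated, but never before injection start
                onset = max(0.0, float(interp_crossing(
                    times[i - 1], times[i], values[i - 1], values[i], thr)))
            else:
                onset = float(times[i])
            break
    if onset is not None and onset > peak_time:
        # pulse already above threshold at its peak; clamp to the peak
        onset = peak_time

    prominence = values[peak_idx] - mu
    hwhm = None
    if prominence > 0:
        level = mu + 0.5 * prominence
        t_l, t_r = width_at_level(values, times, peak_idx, level)
        if t_l is not None and t_r is not None:
            hwhm = float((t_r - t_l) / 2.0)
    return WaveformMetrics(onset=onset, peak_time=peak_time, hwhm=hwhm,
                           peak_value=peak_value)
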