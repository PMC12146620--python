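"""Transcranial cortex-wide Ca²⁺ movie analysis.

Pipeline: spatial binning (512×512 → 64×64), per-ROI ΔF/F against the 50 s
pre-injection baseline, zero-phase 1 Hz low-pass, peak detection above the
baseline level, reference-normalized peak ratios, the activation level
(earliest evoked wave in [3, 8) s over the spontaneous mean), and
oscillation width statistics for the spontaneous [−50, 0) and late
[10, 60) s windows.

ΔF/F = (Ft − F0)/F0 with F0 the mean over the baseline window; traces are
kept as dimensionless fractions (multiply by 100 for percent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import signal as sps

from ._signal import lowpass_zero_phase, window_mask
from .config import RunConfig
from .io import RoiSet


@dataclass
class DffTrace:
    """A ΔF/F time series on a time base relative to injection start."""

    values: np.ndarray
    times: np.ndarray
    baseline_window: tuple[float, float]
    f0: float
    roi: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")
        if self.baseline_window[1] > 0:
            raise ValueError("baseline window must precede injection (t=0)")
        if self.f0 <= 0:
            raise ValueError(f"degenerate baseline: F0 = {self.f0} <= 0")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class PeakEvent:
    """A detected oscillation/transient peak."""

    time: float
    amplitude: float
    width: float  # full width at half prominence, seconds
    prominence: float
    roi: str = ""


@dataclass
class ActivationResult:
    """Per-region activation level: earliest evoked peak ratio over the
    spontaneous mean peak ratio. ``valid`` is False when no matched wave
    fell inside the earliest-wave window (value is then NaN, never a
    substituted later wave)."""

    region: str
    spontaneous_peak_ratio: float
    injection_peak_ratio: float
    activation_level: float
    valid: bool
    n_spontaneous: int = 0
    n_unmatched: int = 0


@dataclass
class WidthResult:
    """Mean oscillation widths in the spontaneous and late windows."""

    spontaneous_mean_width: float
    late_mean_width: float
    spontaneous_widths: np.ndarray = field(default_factory=lambda: np.empty(0))
    late_widths: np.ndarray = field(default_factory=lambda: np.empty(0))
    spontaneous_valid: bool = True
    late_valid: bool = True


# ---------------------------------------------------------------------------

def bin_movie(stack: np.ndarray, target: tuple[int, int] = (64, 64)
              ) -> np.ndarray:
    """Spatially bin a T×H×W stack to T×target by block averaging.

    When the source dimensions are not divisible by the target, the
    bottom/right remainder rows/columns are cropped before averaging.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("movie stack must be T x H x W")
    t, h, w = stack.shape
    th, tw = target
    if th > h or tw > w:
        raise ValueError(f"target grid {target} exceeds image size {(h, w)}")
    bh, bw = h // th, w // tw
    stack = stack[:, : bh * th, : bw * tw]
    return stack.reshape(t, th, bh, tw, bw).mean(axis=(2, 4))


def roi_dff(stack: np.ndarray, rois: RoiSet, frame_rate: float,
            t_injection: float,
            baseline_window: tuple[float, float] = (-50.0, 0.0)
            ) -> Dict[str, DffTrace]:
    """Per-ROI ΔF/F traces: spatial mean over each mask, then
    (Ft − F0)/F0 against the baseline-window mean."""
    stack = np.asarray(stack, dtype=float)
    times = np.arange(stack.shape[0]) / frame_rate - t_injection
    bmask = window_mask(times, *baseline_window)
    if not bmask.any():
        raise ValueError("baseline window contains no frames")
    out: Dict[str, DffTrace] = {}
    for name, mask in rois.masks.items():
        if mask.shape != stack.shape[1:]:
            raise ValueError(f"ROI {name!r} grid {mask.shape} does not match "
                             f"movie frames {stack.shape[1:]}")
        trace = stack[:, mask].mean(axis=1)
        f0 = float(trace[bmask].mean())
        if f0 <= 0:
            raise ValueError(f"ROI {name!r}: degenerate baseline F0={f0}")
        out[name] = DffTrace(values=(trace - f0) / f0, times=times,
                             baseline_window=baseline_window, f0=f0,
                             roi=rois.labels.get(name, name))
    return out


def lowpass(trace: DffTrace, cutoff: float = 1.0) -> DffTrace:
    """Zero-phase low-pass (4th-order Butterworth, unit DC gain)."""
    fs = 1.0 / trace.dt
    filtered = lowpass_zero_phase(trace.values, cutoff, fs)
    return DffTrace(values=filtered, times=trace.times,
                    baseline_window=trace.baseline_window,
                    f0=trace.f0, roi=trace.roi)


def detect_peaks(trace: DffTrace,
                 prominence_min: Optional[float] = None,
                 prominence_sd_mult: float = 0.5) -> List[PeakEvent]:
    """Oscillation peaks exceeding the baseline level.

    Peaks are strict local maxima with ΔF/F > 0 (the baseline level after
    ΔF/F conversion) and topographic prominence ≥ ``prominence_min``; when
    the floor is not given it defaults to ``prominence_sd_mult`` × the
    baseline-window SD of the trace. Widths are full widths at half
    prominence; results are sorted by time.
    """
    x = trace.values
    if prominence_min is None:
        bmask = window_mask(trace.times, *trace.baseline_window)
        prominence_min = prominence_sd_mult * float(x[bmask].std(ddof=0))
    idx, props = sps.find_peaks(x, prominence=max(prominence_min, 0.0))
    keep = x[idx] > 0
    idx = idx[keep]
    if len(idx):
        prom_data = tuple(p[keep] for p in (props["prominences"],
                                            props["left_bases"],
                                            props["right_bases"]))
        widths = sps.peak_widths(x, idx, rel_height=0.5,
                                 prominence_data=prom_data)[0]
        proms = prom_data[0]
    else:
        widths, proms = np.empty(0), np.empty(0)
    dt = trace.dt
    return [PeakEvent(time=float(trace.times[i]), amplitude=float(x[i]),
                      width=float(w * dt), prominence=float(p), roi=trace.roi)
            for i, w, p in zip(idx, widths, proms)]


# ---------------------------------------------------------------------------
# Peak-ratio series and activation level

@dataclass
class RatioSeries:
    """Target peaks matched to reference peaks with amplitude ratios."""

    times: np.ndarray            # matched target peak times
    ratios: np.ndarray           # target amplitude / reference amplitude
    n_unmatched: int
    n_skipped_zero_ref: int
    roi: str = ""


def match_peaks(target_times: np.ndarray, ref_times: np.ndarray,
                tolerance: float) -> List[tuple[int, int]]:
    """One-to-one target→reference pairing by time proximity.

    Maximizes the number of pairs with \\|Δt\\| ≤ tolerance and, among such
    pairings, minimizes the total \\|Δt\\| (solved as a linear assignment);
    exact ties broken toward the earlier reference peak.
    """
    nt, nr = len(target_times), len(ref_times)
    if nt == 0 or nr == 0:
        return []
    dt = np.abs(np.subtract.outer(np.asarray(target_times, float),
                                  np.asarray(ref_times, float)))
    big = 1e9
    cost = np.where(dt <= tolerance, dt, big)
    # nudge toward earlier reference peaks on exact ties
    cost = cost + np.arange(nr)[None, :] * (tolerance * 1e-12 + 1e-15)
    rows, cols = optimize.linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if dt[r, c] <= tolerance]


def peak_ratio_series(target: List[PeakEvent], reference: List[PeakEvent],
                      tolerance: Optional[float] = None) -> RatioSeries:
    """Amplitude ratios of target peaks over their nearest-in-time reference
    peaks.

    Default matching tolerance is half the median reference inter-peak
    interval; unmatched target peaks are dropped and counted, pairs with a
    zero reference amplitude are skipped and counted.
    """
    if not reference:
        raise ValueError("reference ROI has no peaks")
    ref_times = np.array([p.time for p in reference])
    if tolerance is None:
        if len(ref_times) > 1:
            tolerance = 0.5 * float(np.median(np.diff(np.sort(ref_times))))
        else:
            tolerance = np.inf
    pairs = match_peaks(np.array([p.time for p in target]), ref_times,
                        tolerance)
    times, ratios = [], []
    skipped = 0
    for ti, ri in pairs:
        ref_amp = reference[ri].amplitude
        if ref_amp == 0:
            skipped += 1
            continue
        times.append(target[ti].time)
        ratios.append(target[ti].amplitude / ref_amp)
    order = np.argsort(times)
    roi = target[0].roi if target else ""
    return RatioSeries(times=np.asarray(times, float)[order],
                       ratios=np.asarray(ratios, float)[order],
                       n_unmatched=len(target) - len(pairs),
                       n_skipped_zero_ref=skipped, roi=roi)


def activation_level(series: RatioSeries,
                     earliest_wave_window: tuple[float, float] = (3.0, 8.0),
                     spontaneous_window: tuple[float, float] = (-50.0, 0.0),
                     region: str = "") -> ActivationResult:
    """Earliest evoked peak ratio divided by the spontaneous mean ratio.

    The injection ratio is that of the earliest matched wave inside the
    earliest-wave window; with no wave there the result is flagged invalid
    (NaN) rather than substituting a later wave.
    """
    sp = window_mask(series.times, *spontaneous_window)
    if not sp.any():
        raise ValueError("no matched peaks in the spontaneous window")
    spont = float(series.ratios[sp].mean())
    inj = window_mask(series.times, *earliest_wave_window)
    if inj.any():
        first = np.flatnonzero(inj)[0]
        inj_ratio = float(series.ratios[first])
        level = inj_ratio / spont
        valid = True
    else:
        inj_ratio, level, valid = np.nan, np.nan, False
    return ActivationResult(region=region or series.roi,
                            spontaneous_peak_ratio=spont,
                            injection_peak_ratio=inj_ratio,
                            activation_level=level, valid=valid,
                            n_spontaneous=int(sp.sum()),
                            n_unmatched=series.n_unmatched)


def wave_widths(trace: DffTrace, osc_threshold: float = 0.02,
                spontaneous_window: tuple[float, float] = (-50.0, 0.0),
                late_window: tuple[float, float] = (10.0, 60.0),
                prominence_min: Optional[float] = None) -> WidthResult:
    """Width statistics of Ca²⁺ oscillations above an amplitude threshold.

    ``osc_threshold`` is in trace units (ΔF/F fraction; the config default
    of 2 percent ΔF/F corresponds to 0.02 here). A window with no
    oscillation yields NaN and a cleared validity flag.
    """
    peaks = [p for p in detect_peaks(trace, prominence_min=prominence_min)
             if p.amplitude > osc_threshold]
    t = np.array([p.time for p in peaks])
    w = np.array([p.width for p in peaks])
    sw = w[window_mask(t, *spontaneous_window)] if len(t) else np.empty(0)
    lw = w[window_mask(t, *late_window)] if len(t) else np.empty(0)
    return WidthResult(
        spontaneous_mean_width=float(sw.mean()) if len(sw) else np.nan,
        late_mean_width=float(lw.mean()) if len(lw) else np.nan,
        spontaneous_widths=sw, late_widths=lw,
        spontaneous_valid=bool(len(sw)), late_valid=bool(len(lw)))


# ---------------------------------------------------------------------------
# Whole-movie pipeline

def analyze_movie(stack: np.ndarray, rois: RoiSet, frame_rate: float,
                  t_injection: float, config: Optional[RunConfig] = None
                  ) -> pd.DataFrame:
    """Run binning → ΔF/F → low-pass → peaks → ratios → activation/widths.

    Returns a tidy per-region table with activation levels and mean wave
    widths. The movie is binned only when larger than 64×64. Requires a
    Reference-labeled ROI.
    """
    config = config or RunConfig()
    if stack.shape[1:] != (64, 64) and stack.shape[1] >= 64 and stack.shape[2] >= 64:
        stack = bin_movie(stack, (64, 64))
    bw = (-config.baseline_widefield, 0.0)
    traces = roi_dff(stack, rois, frame_rate, t_injection, baseline_window=bw)
    filtered = {n: lowpass(tr, config.lpf_cutoff) for n, tr in traces.items()}
    peaks = {n: detect_peaks(tr, prominence_sd_mult=config.prominence_sd_mult)
             for n, tr in filtered.items()}
    ref_name = rois.reference_name()
    rows = []
    for name, tr in filtered.items():
        region = rois.labels.get(name, name)
        if name == ref_name:
            act = ActivationResult(region=region, spontaneous_peak_ratio=1.0,
                                   injection_peak_ratio=1.0,
                                   activation_level=1.0, valid=True)
        else:
            series = peak_ratio_series(peaks[name], peaks[ref_name])
            act = activation_level(series, config.earliest_wave_window,
                                   config.spontaneous_window, region=region)
        widths = wave_widths(tr, osc_threshold=config.osc_threshold / 100.0,
                             spontaneous_window=config.spontaneous_window,
                             late_window=config.late_widefield)
        rows.append({
            "roi": name, "region": region,
            "spontaneous_peak_ratio": act.spontaneous_peak_ratio,
            "injection_peak_ratio": act.injection_peak_ratio,
            "activation_level": act.activation_level,
            "valid": act.valid,
            "n_unmatched": act.n_unmatched,
            "spontaneous_mean_width_s": widths.spontaneous_mean_width,
            "late_mean_width_s": widths.late_mean_width,
        })
    return pd.DataFrame(rows)
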