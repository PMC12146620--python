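"""Single-cell two-photon Ca²⁺ trace analysis.

Each cell's ΔF/F trace is classified against its own spontaneous (baseline)
statistics: any sample above mean + 0.5 SD inside the 15–38 s post-injection
window labels the cell ``Increase``, any sample below mean − 0.5 SD labels
it ``Decrease``, neither labels it ``Nonresponse``. Cells crossing both
thresholds are assigned by the larger absolute excursion (tie → Increase).
Per-animal label proportions and class-average waveform metrics (onset,
peak time, HWHM) complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._signal import WaveformMetrics, pulse_metrics, window_mask

LABELS = ("Increase", "Decrease", "Nonresponse")


@dataclass
class CellResponseLabel:
    """Label and excursion metrics (in baseline-SD units) of one cell."""

    cell: str
    label: str
    max_pos_z: float
    max_neg_z: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def dff_from_raw(traces: np.ndarray, times: np.ndarray,
                 baseline_window: tuple[float, float]) -> np.ndarray:
    """Per-cell ΔF/F = (Ft − F0)/F0 with F0 the baseline-window mean."""
    traces = np.asarray(traces, dtype=float)
    bmask = window_mask(times, *baseline_window)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    f0 = traces[:, bmask].mean(axis=1, keepdims=True)
    if np.any(f0 <= 0):
        bad = np.flatnonzero(f0[:, 0] <= 0)
        raise ValueError(f"degenerate baseline F0 <= 0 for cells {bad.tolist()}")
    return (traces - f0) / f0


def classify_cells(traces: np.ndarray, times: np.ndarray,
                   baseline_window: tuple[float, float] = (-50.0, 0.0),
                   class_window: tuple[float, float] = (15.0, 38.0),
                   sd_mult: float = 0.5,
                   min_dwell: int = 0,
                   cell_ids: Optional[Sequence[str]] = None
                   ) -> List[CellResponseLabel]:
    """Increase / Decrease / Nonresponse labels for a cells × time matrix.

    ``min_dwell`` is the number of consecutive supra-threshold samples
    required (0 or 1: a single sample suffices). A zero-variance baseline
    is an error naming the cell.
    """
    traces = np.asarray(traces, dtype=float)
    times = np.asarray(times, dtype=float)
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(traces.shape[0])]
    bmask = window_mask(times, *baseline_window)
    wmask = window_mask(times, *class_window)
    if not bmask.any() or not wmask.any():
        raise ValueError("baseline or classification window has no samples")
    out: List[CellResponseLabel] = []
    for i, cid in enumerate(cell_ids):
        x = traces[i]
        mu = x[bmask].mean()
        sd = x[bmask].std(ddof=0)
        if sd == 0:
            raise ValueError(f"cell {cid!r}: zero-variance baseline")
        z = (x[wmask] - mu) / sd
        up = z > sd_mult
        down = z < -sd_mult
        if min_dwell > 1:
            up = _dwell(up, min_dwell)
            down = _dwell(down, min_dwell)
        max_pos = float(z.max())
        max_neg = float(z.min())
        if up.any() and down.any():
            label = "Increase" if max_pos >= -max_neg else "Decrease"
        elif up.any():
            label = "Increase"
        elif down.any():
            label = "Decrease"
        else:
            label = "Nonresponse"
        out.append(CellResponseLabel(cell=cid, label=label,
                                     max_pos_z=max_pos, max_neg_z=max_neg,
                                     window=class_window))
    return out


def _dwell(mask: np.ndarray, n: int) -> np.ndarray:
    """True where ``mask`` holds for at least ``n`` consecutive samples."""
    if not mask.any():
        return mask
    run = np.zeros(len(mask), dtype=int)
    for i, m in enumerate(mask):
        run[i] = run[i - 1] + 1 if m and i else int(m)
    return run >= n


def response_proportions(labels: Sequence[CellResponseLabel],
                         animals: Optional[Sequence[str]] = None
                         ) -> pd.DataFrame:
    """Per-animal fraction of each label; fractions sum to 1 per animal."""
    if not labels:
        raise ValueError("no labels given")
    if animals is None:
        animals = ["animal0"] * len(labels)
    df = pd.DataFrame({"animal": list(animals),
                       "label": [l.label for l in labels]})
    counts = (df.groupby(["animal", "label"]).size()
                .unstack(fill_value=0)
                .reindex(columns=LABELS, fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns.name = None
    return props.reset_index()


def average_waveform_metrics(traces: np.ndarray, times: np.ndarray,
                             label: str,
                             baseline_window: tuple[float, float] = (-50.0, 0.0),
                             sd_mult: float = 0.5,
                             search_window: Optional[tuple[float, float]] = None
                             ) -> WaveformMetrics:
    """Waveform metrics of the class-average trace.

    The mean trace across the class's cells is taken; onset is the first
    post-injection crossing of the mean-trace baseline mean ± ``sd_mult``·SD
    (sign per class), peak time the argmax (Increase) or argmin (Decrease),
    and HWHM half the width at half prominence.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] == 0:
        raise ValueError(f"no traces in class {label!r}")
    mean_trace = traces.mean(axis=0)
    polarity = -1 if label == "Decrease" else +1
    return pulse_metrics(mean_trace, times, baseline_window,
                         polarity=polarity, sd_mult=sd_mult,
                         search_window=search_window)


def analyze_cells(traces: np.ndarray, times: np.ndarray,
                  animals: Optional[Sequence[str]] = None,
                  raw: bool = True,
                  baseline_window: tuple[float, float] = (-50.0, 0.0),
                  class_window: tuple[float, float] = (15.0, 38.0),
                  sd_mult: float = 0.5,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, Dict[str, WaveformMetrics]]:
    """Full per-cell pipeline: (labels table, per-animal proportions,
    per-class waveform metrics). ``raw=True`` converts to ΔF/F first."""
    if raw:
        traces = dff_from_raw(traces, times, baseline_window)
    labels = classify_cells(traces, times, baseline_window, class_window,
                            sd_mult)
    label_df = pd.DataFrame(
        {"cell": [l.cell for l in labels],
         "animal": list(animals) if animals is not None
         else ["animal0"] * len(labels),
         "label": [l.label for l in labels],
         "max_pos_z": [l.max_pos_z for l in labels],
         "max_neg_z": [l.max_neg_z for l in labels]})
    props = response_proportions(labels, animals)
    metrics: Dict[str, WaveformMetrics] = {}
    for cls in ("Increase", "Decrease"):
        rows = [i for i, l in enumerate(labels) if l.label == cls]
        if rows:
            metrics[cls] = average_waveform_metrics(
                traces[rows], times, cls, baseline_window, sd_mult)
    return label_df, props, metrics
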