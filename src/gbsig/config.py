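"""Run configuration: every window and threshold the pipelines use.

All times are in seconds relative to injection start (t = 0 at the start of
the infusion); windows are half-open ``[a, b)``, negative times are
pre-injection. Defaults are the analysis constants used throughout the
study design this package implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import yaml

Window = Tuple[float, float]


@dataclass
class RunConfig:
    """All window/threshold parameters with their standard defaults.

    Parameters
    ----------
    baseline_widefield:
        Pre-injection baseline used for wide-field ΔF/F, seconds (F0 window
        is ``[-baseline_widefield, 0)``).
    baseline_photometry, baseline_ephys:
        Pre-injection baselines for photometry ΔF/F and nerve normalization.
    earliest_wave_window:
        Post-injection window in which the earliest evoked cortical wave is
        sought for the activation level.
    late_widefield:
        Late post-injection window for wave-width statistics.
    late_neuron:
        Late window for the within-animal neuronal late-phase comparison.
    tp_class_window, tp_sd_mult:
        Two-photon Increase/Decrease classification window and SD multiplier.
    photometry_sd_mult:
        SD multiplier for photometry up/down-regulation crossing detection.
    ephys_peak_sd, ephys_noise_sd:
        Nerve peak-counting band: peaks above median + ``ephys_peak_sd``·SD
        are counted, peaks above median + ``ephys_noise_sd``·SD are removed
        as noise artifacts.
    hpf_cutoff, lpf_cutoff:
        Nerve high-pass and wide-field low-pass cutoffs, Hz.
    osc_threshold:
        Wide-field oscillation amplitude threshold in percent ΔF/F.
    prominence_sd_mult:
        Peak prominence floor as a multiple of the baseline-window SD
        (noise-peak suppression in wide-field peak detection).
    min_dwell:
        Minimum number of consecutive supra-threshold samples required by
        the two-photon classifier (0 = a single sample suffices).
    refractory:
        Minimum inter-peak distance for nerve peak counting, seconds.
    injection_duration:
        Duration of the infusion, seconds.
    """

    baseline_widefield: float = 50.0
    baseline_photometry: float = 30.0
    baseline_ephys: float = 30.0
    earliest_wave_window: Window = (3.0, 8.0)
    late_widefield: Window = (10.0, 60.0)
    late_neuron: Window = (30.0, 80.0)
    spontaneous_window: Window = (-50.0, 0.0)
    tp_class_window: Window = (15.0, 38.0)
    tp_sd_mult: float = 0.5
    photometry_sd_mult: float = 3.0
    ephys_peak_sd: float = 2.0
    ephys_noise_sd: float = 5.0
    hpf_cutoff: float = 50.0
    lpf_cutoff: float = 1.0
    osc_threshold: float = 2.0  # percent ΔF/F
    prominence_sd_mult: float = 0.5
    min_dwell: int = 0
    refractory: float = 1e-3
    injection_duration: float = 8.0
    rng_seed: Optional[int] = None
    frame_rate_fallback: Optional[float] = None
    ratiometric_numerator: str = "yellow"
    ratiometric_denominator: str = "cyan"

    def __post_init__(self) -> None:
        for name in ("earliest_wave_window", "late_widefield", "late_neuron",
                     "spontaneous_window", "tp_class_window"):
            a, b = getattr(self, name)
            if not b > a:
                raise ValueError(f"{name} must have positive length, got [{a}, {b})")
        for name in ("tp_sd_mult", "photometry_sd_mult", "ephys_peak_sd",
                     "ephys_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hpf_cutoff", "lpf_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ephys_noise_sd <= self.ephys_peak_sd:
            raise ValueError("ephys_noise_sd must exceed ephys_peak_sd")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
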