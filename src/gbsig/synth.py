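"""Ground-truth-labeled synthetic recordings for all four modalities.

Each generator is a pure function of its parameters and seed and emulates
the statistical structure the corresponding analysis assumes:

* wide-field — a global slow (≈0.2 Hz) cortical oscillation with phase
  jitter, shared by all regions with occipital > frontal amplitude, plus an
  optional frontal-only evoked transient shortly after injection and i.i.d.
  Gaussian pixel noise;
* photometry — a transient neuronal pulse (optionally with a sustained late
  plateau) or a biphasic astrocytic response (rise followed by an
  undershoot starting ≈40 s post-injection), with drift and noise, single
  channel or dual-channel ratiometric;
* two-photon — a mixture of Increase / Decrease / Nonresponse cells, the
  Decrease onset lagging the Increase onset by ≈9 s; every cell carries
  zero-mean spontaneous fluctuation bursts in the pre-injection epoch
  (these set the baseline SD the ±0.5 SD classifier is scaled by, while
  leaving the baseline mean at the resting level);
* nerve — inhomogeneous-Poisson afferent spikes (rate × evoked multiplier
  in the post window) convolved with a 0.8 ms biphasic unit waveform,
  bounded (uniform) background noise, and sparse large artifacts above the
  +5 SD exclusion line.

The background noise of the nerve generator is bounded by design: the
counting threshold (spontaneous median + 2 SD) then sits above the noise
ceiling, so counted peaks are unit spikes rather than noise excursions, as
the counting rule assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io import Recording, RoiSet


@dataclass
class SynthParams:
    """Parameters of the synthetic recording generators.

    Only the fields relevant to a given modality are read by its generator.
    Times in seconds, rates in events/s, amplitudes in ΔF/F units (imaging)
    or arbitrary voltage units (nerve).
    """

    modality: str = "widefield"
    duration: float = 130.0
    sampling_rate: float = 10.0
    t_injection: float = 60.0
    seed: Optional[int] = None
    noise_sd: float = 0.0

    # wide-field
    osc_freq: float = 0.2
    osc_amp: Dict[str, float] = field(default_factory=lambda: {
        "Frontal": 0.030, "Somato": 0.035, "Reference": 0.030,
        "RSC": 0.045, "Visual": 0.050, "background": 0.030})
    phase_jitter: float = 0.05     # rad per frame, random-walk increments
    evoked_amp: float = 0.0        # ΔF/F, frontal-only transient
    evoked_delay: float = 4.5      # s after injection start
    evoked_sigma: float = 0.8      # s, Gaussian transient width
    base_intensity: float = 100.0

    # photometry
    neuron_pulse: Dict[str, float] = field(default_factory=lambda: {
        "amplitude": 0.30, "onset": 2.0, "decay": 8.0, "plateau": 0.0})
    astro_biphasic: Dict[str, float] = field(default_factory=lambda: {
        "rise_amp": 0.30, "rise_onset": 5.0, "rise_decay": 8.0,
        "undershoot_amp": 0.10, "undershoot_onset": 40.0,
        "undershoot_decay": 15.0})
    drift_per_s: float = 2e-5      # ΔF/F per second, linear
    ratiometric: bool = False

    # two-photon
    cell_mix: Tuple[float, float, float] = (0.2, 0.5, 0.3)
    increase_amp: float = 0.20
    increase_onset: float = 18.0   # s post-injection
    increase_decay: float = 7.0    # alpha-function time constant
    decrease_amp: float = 0.15
    decrease_lag: float = 9.0      # Decrease onset delay vs Increase
    spont_event_amp: float = 0.08
    spont_event_period: float = 4.0
    spont_events_per_cell: int = 2

    # nerve (ephys)
    baseline_rate: float = 15.0
    evoked_multiplier: float = 3.0
    evoked_window: Tuple[float, float] = (0.0, 6.0)
    spike_amp: float = 1.0
    spike_amp_jitter: float = 0.1  # lognormal sigma
    spike_width: float = 8e-4      # s, biphasic (one sine cycle)
    artifact_rate: float = 0.2     # events/s, whole record
    artifact_amp: float = 4.0
    artifact_width: float = 3e-4   # s, Gaussian blip

    def __post_init__(self) -> None:
        if abs(sum(self.cell_mix) - 1.0) > 1e-9:
            raise ValueError("cell_mix proportions must sum to 1")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be > 0")
        if not 0 <= self.t_injection < self.duration:
            raise ValueError("t_injection must lie within the record")
        if self.evoked_multiplier < 0:
            raise ValueError("evoked_multiplier must be >= 0")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.astro_biphasic["undershoot_onset"] <= 0:
            raise ValueError("undershoot must start after injection")
        for key in ("rise_decay", "undershoot_decay"):
            if self.astro_biphasic[key] <= 0:
                raise ValueError(f"astro_biphasic[{key!r}] must be > 0")
        if self.neuron_pulse["decay"] <= 0:
            raise ValueError("neuron pulse decay must be > 0")


@dataclass
class GroundTruth:
    """True labels, effect sizes and event times behind a synthetic record."""

    modality: str
    seed: Optional[int]
    evoked_amp: Optional[float] = None
    evoked_time: Optional[float] = None
    cell_labels: Optional[List[str]] = None
    pulse_params: Optional[dict] = None
    spike_times: Optional[np.ndarray] = None
    artifact_times: Optional[np.ndarray] = None
    true_rate_ratio: Optional[float] = None
    evoked_window: Optional[Tuple[float, float]] = None


def _alpha(t: np.ndarray, t0: float, tau: float) -> np.ndarray:
    """Normalized alpha function: peaks at 1 at t = t0 + tau."""
    u = (t - t0) / tau
    return np.where(u > 0, u * np.exp(1.0 - u), 0.0)


# ---------------------------------------------------------------------------
# Wide-field

def default_roiset(grid: tuple[int, int] = (64, 64)) -> RoiSet:
    """Rectangular stand-in cortical regions on the binned grid (synthetic
    layout, not an atlas registration): frontal anterior, somatosensory and
    auditory-reference lateral, retrosplenial medial-posterior, visual
    posterior."""
    h, w = grid

    def rect(r0, r1, c0, c1):
        m = np.zeros(grid, dtype=bool)
        m[r0:r1, c0:c1] = True
        return m

    masks = {
        "Frontal": rect(4, 14, 20, 44),
        "Somato": rect(20, 30, 8, 24),
        "Reference": rect(34, 42, 2, 12),
        "RSC": rect(40, 56, 27, 37),
        "Visual": rect(46, 60, 42, 58),
    }
    labels = {n: n for n in masks}
    return RoiSet(masks=masks, labels=labels)


def gen_widefield(params: SynthParams, seed: Optional[int] = None
                  ) -> tuple[np.ndarray, RoiSet, GroundTruth]:
    """Synthetic wide-field movie (T×64×64), its RoiSet and ground truth."""
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    fs = params.sampling_rate
    if params.osc_freq >= fs / 2:
        raise ValueError("osc_freq must be below Nyquist")
    if params.t_injection + params.evoked_delay > params.duration:
        raise ValueError("evoked transient falls outside the record")
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs - params.t_injection
    grid = (64, 64)
    rois = default_roiset(grid)

    phase = np.cumsum(rng.normal(0.0, params.phase_jitter, n))
    phase += rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * params.osc_freq * (t + params.t_injection)
                  + phase)

    amp_map = np.full(grid, params.osc_amp.get("background", 0.03))
    for name, mask in rois.masks.items():
        amp_map[mask] = params.osc_amp[name]

    evoked_time = params.evoked_delay
    evoked = params.evoked_amp * np.exp(
        -0.5 * ((t - evoked_time) / params.evoked_sigma) ** 2)
    evoked_map = rois.masks["Frontal"].astype(float)

    b = params.base_intensity
    movie = b * (1.0
                 + amp_map[None, :, :] * wave[:, None, None]
                 + evoked_map[None, :, :] * evoked[:, None, None])
    if params.noise_sd > 0:
        movie = movie + rng.normal(0.0, params.noise_sd, movie.shape)
    gt = GroundTruth(modality="widefield", seed=seed,
                     evoked_amp=params.evoked_amp, evoked_time=evoked_time)
    return movie, rois, gt


# ---------------------------------------------------------------------------
# Photometry

def gen_photometry(params: SynthParams, cell_type: str = "neuron",
                   seed: Optional[int] = None
                   ) -> tuple[Recording, GroundTruth]:
    """Synthetic fiber-photometry recording for one animal.

    ``neuron``: a single alpha-function pulse after injection plus an
    optional sustained plateau. ``astrocyte``: a rise pulse followed by a
    negative undershoot from ≈40 s post-injection. Additive linear drift
    and Gaussian noise (low-passed for kHz-rate astrocyte records so its
    correlation time matches slow indicator dynamics); dual-channel
    yellow/cyan output when ``params.ratiometric`` is set.
    """
    if cell_type not in ("neuron", "astrocyte"):
        raise ValueError(f"unknown cell_type {cell_type!r}")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs - params.t_injection

    if cell_type == "neuron":
        p = params.neuron_pulse
        s = p["amplitude"] * _alpha(t, p["onset"], p["decay"])
        if p.get("plateau", 0.0):
            s = s + p["plateau"] / (1.0 + np.exp(-(t - 25.0) / 4.0))
        pulse_params = dict(p)
    else:
        p = params.astro_biphasic
        s = (p["rise_amp"] * _alpha(t, p["rise_onset"], p["rise_decay"])
             - p["undershoot_amp"] * _alpha(t, p["undershoot_onset"],
                                            p["undershoot_decay"]))
        pulse_params = dict(p)

    s = s + params.drift_per_s * (t - t[0])
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, n)
        if fs > 20.0:
            from ._signal import lowpass_zero_phase
            noise = lowpass_zero_phase(noise, 2.0, fs)
            # restore the requested sd after smoothing
            noise *= params.noise_sd / max(noise.std(), 1e-30)
        s = s + noise

    if params.ratiometric:
        y0 = 300.0
        samples = np.vstack([y0 * (1.0 + s / 2.0), y0 * (1.0 - s / 2.0)])
        roles = {"yellow": 0, "cyan": 1}
    else:
        samples = 100.0 * (1.0 + s)
        roles = None
    rec = Recording(samples=samples, sampling_rate=fs,
                    t_injection=params.t_injection, modality="photometry",
                    channel_roles=roles)
    gt = GroundTruth(modality="photometry", seed=seed,
                     pulse_params={"cell_type": cell_type, **pulse_params})
    return rec, gt


# ---------------------------------------------------------------------------
# Two-photon

def gen_twophoton(params: SynthParams, n_cells: int,
                  seed: Optional[int] = None
                  ) -> tuple[np.ndarray, GroundTruth]:
    """Synthetic per-cell raw fluorescence matrix (cells × time) + labels.

    Cells are drawn from ``cell_mix``; Increase cells receive a positive
    alpha transient peaking inside the 15–38 s classification window,
    Decrease cells a negative deflection whose onset lags by
    ``decrease_lag`` (≈9 s), Nonresponse cells only background. Every cell
    carries ``spont_events_per_cell`` spontaneous fluctuation bursts (one
    zero-integral sine cycle each) in the pre-injection epoch: they set the
    baseline SD without biasing the baseline mean away from the resting
    level.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs - params.t_injection

    labels = rng.choice(["Increase", "Decrease", "Nonresponse"],
                        size=n_cells, p=list(params.cell_mix))
    traces = np.empty((n_cells, n))
    period = params.spont_event_period
    t_bl_lo = -min(params.t_injection - 2.0, 48.0)
    for i, label in enumerate(labels):
        s = np.zeros(n)
        for _ in range(params.spont_events_per_cell):
            t0 = rng.uniform(t_bl_lo, -10.0 - period)
            u = (t - t0) / period
            burst = np.where((u > 0) & (u < 1),
                             np.sin(2 * np.pi * u), 0.0)
            s += params.spont_event_amp * burst
        if label == "Increase":
            s += params.increase_amp * _alpha(t, params.increase_onset,
                                              params.increase_decay)
        elif label == "Decrease":
            s -= params.decrease_amp * _alpha(
                t, params.increase_onset + params.decrease_lag,
                params.increase_decay)
        if params.noise_sd > 0:
            s = s + rng.normal(0.0, params.noise_sd, n)
        traces[i] = 100.0 * (1.0 + s)
    gt = GroundTruth(modality="twophoton", seed=seed,
                     cell_labels=[str(l) for l in labels])
    return traces, gt


# ---------------------------------------------------------------------------
# Nerve (ephys)

def gen_ephys(params: SynthParams, seed: Optional[int] = None
              ) -> tuple[Recording, GroundTruth]:
    """Synthetic vagus-nerve recording.

    Spike times are inhomogeneous Poisson: ``baseline_rate`` outside the
    evoked window, ``baseline_rate × evoked_multiplier`` inside it (the
    window is relative to injection start). Each spike adds a biphasic
    0.8 ms waveform with lognormal amplitude jitter. Background noise is
    bounded uniform; artifacts are sparse large monophasic blips whose
    amplitude puts them above the +5 SD exclusion line.
    """
    seed = params.seed if seed is None else seed
    if params.sampling_rate < 1000:
        raise ValueError("nerve generator needs kHz-range sampling")
    rng = np.random.default_rng(seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    t_rel = np.arange(n) / fs - params.t_injection

    # piecewise-constant rate -> Poisson spike times
    w0, w1 = params.evoked_window
    segs = [(-params.t_injection, w0, params.baseline_rate),
            (w0, w1, params.baseline_rate * params.evoked_multiplier),
            (w1, params.duration - params.t_injection, params.baseline_rate)]
    spike_times = []
    for a, b, rate in segs:
        if b <= a or rate <= 0:
            continue
        k = rng.poisson(rate * (b - a))
        spike_times.append(rng.uniform(a, b, k))
    spike_times = np.sort(np.concatenate(spike_times)) if spike_times \
        else np.empty(0)

    x = np.zeros(n)
    wlen = max(int(round(params.spike_width * fs)), 2)
    tw = np.arange(wlen) / fs
    template = np.sin(2 * np.pi * tw / params.spike_width)
    for ts in spike_times:
        i0 = int(round((ts + params.t_injection) * fs))
        if i0 < 0 or i0 + wlen > n:
            continue
        amp = params.spike_amp * rng.lognormal(0.0, params.spike_amp_jitter)
        x[i0:i0 + wlen] += amp * template

    n_art = rng.poisson(params.artifact_rate * params.duration)
    artifact_times = np.sort(rng.uniform(t_rel[0] + 0.01,
                                         t_rel[-1] - 0.01, n_art))
    alen = max(int(round(params.artifact_width * fs * 6)), 3)
    ta = (np.arange(alen) - alen // 2) / fs
    blip = np.exp(-0.5 * (ta / params.artifact_width) ** 2)
    for ts in artifact_times:
        i0 = int(round((ts + params.t_injection) * fs)) - alen // 2
        if i0 < 0 or i0 + alen > n:
            continue
        x[i0:i0 + alen] += params.artifact_amp * blip

    if params.noise_sd > 0:
        # bounded noise: uniform on [-c, c] with sd = noise_sd
        c = params.noise_sd * np.sqrt(3.0)
        x = x + rng.uniform(-c, c, n)

    rec = Recording(samples=x, sampling_rate=fs,
                    t_injection=params.t_injection, modality="ephys")
    gt = GroundTruth(modality="ephys", seed=seed,
                     spike_times=spike_times,
                     artifact_times=artifact_times,
                     true_rate_ratio=params.evoked_multiplier,
                     evoked_window=params.evoked_window)
    return rec, gt


def widefield_default_params(**overrides) -> SynthParams:
    """Wide-field defaults: 130 s at 10 Hz, injection at 60 s, 0.2 Hz slow
    wave, evoked frontal transient of 0.1 ΔF/F peaking 4.5 s post-injection,
    pixel noise sd 0.5 on a base intensity of 100."""
    defaults = dict(modality="widefield", duration=130.0, sampling_rate=10.0,
                    t_injection=60.0, noise_sd=0.5, evoked_amp=0.1)
    defaults.update(overrides)
    return SynthParams(**defaults)


def photometry_default_params(cell_type: str = "neuron",
                              **overrides) -> SynthParams:
    """Photometry defaults: 150 s record, injection at 60 s; neurons are
    single-channel at 1 Hz, astrocytes dual-channel ratiometric at 1 kHz;
    noise sd 0.01 ΔF/F."""
    defaults = dict(modality="photometry", duration=150.0, t_injection=60.0,
                    noise_sd=0.01,
                    sampling_rate=1.0 if cell_type == "neuron" else 1000.0,
                    ratiometric=cell_type == "astrocyte")
    defaults.update(overrides)
    return SynthParams(**defaults)


def twophoton_default_params(**overrides) -> SynthParams:
    """Two-photon defaults: 150 s at 10 Hz, injection at 60 s, cell mix
    (0.2, 0.5, 0.3), fast noise sd 0.003 ΔF/F (small against the ≈0.03
    baseline SD set by spontaneous transients, keeping spurious ±0.5 SD
    crossings rare)."""
    defaults = dict(modality="twophoton", duration=150.0, sampling_rate=10.0,
                    t_injection=60.0, noise_sd=0.003)
    defaults.update(overrides)
    return SynthParams(**defaults)


def ephys_default_params(**overrides) -> SynthParams:
    """Nerve-recording defaults: 45 s at 20 kHz, injection at 35 s,
    baseline 15 spikes/s, evoked ×3 in [0, 6) s, uniform noise sd 0.29
    (ceiling 0.5) under unit spike amplitude."""
    defaults = dict(modality="ephys", duration=45.0, sampling_rate=20000.0,
                    t_injection=35.0, noise_sd=0.5 / np.sqrt(3.0))
    defaults.update(overrides)
    return SynthParams(**defaults)
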