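"""Domain containers and readers/writers for the external formats:
TIFF movies, ImageJ ROI archives, trace tables (CSV/HDF5), and JSON run
manifests.

A :class:`Recording` is one time-series acquisition (any modality); a
:class:`RoiSet` is a set of named region masks on the binned image grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import tifffile

from . import imagej_roi
from .config import RunConfig

REGIONS = ("Frontal", "Somato", "Visual", "RSC", "Reference")
MODALITIES = ("widefield", "twophoton", "photometry", "ephys")


@dataclass
class Recording:
    """A single-site time-series recording.

    ``samples`` is (n_samples,) for single-channel data or
    (n_channels, n_samples) for multi-channel (e.g. ratiometric yellow/cyan)
    data; ``channel_roles`` maps a role name to its row index.
    ``t_injection`` is seconds from record start to injection start.
    """

    samples: np.ndarray
    sampling_rate: float
    t_injection: float
    injection_duration: float = 8.0
    modality: str = "photometry"
    channel_roles: Optional[Dict[str, int]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D or (channels, samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not 0 <= self.t_injection < self.duration:
            raise ValueError("t_injection must lie within the record")
        if self.channel_roles:
            nch = 1 if self.samples.ndim == 1 else self.samples.shape[0]
            for role, idx in self.channel_roles.items():
                if not 0 <= idx < nch:
                    raise ValueError(f"channel role {role!r} index {idx} "
                                     f"out of range for {nch} channel(s)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration(self) -> float:
        return self.samples.shape[-1] / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to injection start."""
        return np.arange(self.n_samples) / self.sampling_rate - self.t_injection

    def channel(self, role: str) -> np.ndarray:
        if not self.channel_roles or role not in self.channel_roles:
            raise KeyError(f"recording has no channel role {role!r}")
        return self.samples[self.channel_roles[role]]


@dataclass
class RoiSet:
    """Named boolean masks on an image grid, with region labels.

    ``labels`` maps mask name -> region label (one of ``REGIONS``). Exactly
    one mask may carry the ``Reference`` label; peak-ratio analysis requires
    it to be present.
    """

    masks: Dict[str, np.ndarray]
    labels: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one grid shape")
        for name, mask in self.masks.items():
            if not mask.any():
                raise ValueError(f"ROI {name!r} has an empty mask")
        for name, region in self.labels.items():
            if name not in self.masks:
                raise ValueError(f"label for unknown ROI {name!r}")
            if region not in REGIONS:
                raise ValueError(f"unknown region label {region!r}")
        refs = [n for n, r in self.labels.items() if r == "Reference"]
        if len(refs) > 1:
            raise ValueError(f"duplicate Reference label: {refs}")

    @property
    def grid(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def reference_name(self) -> str:
        for name, region in self.labels.items():
            if region == "Reference":
                return name
        raise ValueError("RoiSet has no ROI labeled 'Reference' "
                         "(required for peak-ratio analysis)")

    def by_region(self) -> Dict[str, np.ndarray]:
        return {self.labels.get(n, n): m for n, m in self.masks.items()}


# ---------------------------------------------------------------------------
# TIFF movies

def write_movie(path: str | Path, stack: np.ndarray, frame_rate: float) -> None:
    """Write a T×H×W stack as an ImageJ-style TIFF with fps metadata."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("movie stack must be T x H x W")
    tifffile.imwrite(path, stack, imagej=stack.dtype in (np.uint8, np.uint16),
                     photometric="minisblack",
                     metadata={"axes": "TYX", "fps": float(frame_rate)})


def read_movie(path: str | Path,
               frame_rate: Optional[float] = None
               ) -> tuple[np.ndarray, float]:
    """Read a TIFF stack; returns (T×H×W array, frame rate in Hz).

    The frame rate comes from the TIFF's ImageJ/shaped metadata (``fps`` or
    ``finterval``); pass ``frame_rate`` to override or when the file has no
    usable metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.imagej_metadata or tf.shaped_metadata and tf.shaped_metadata[0] or {}
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a T x H x W stack, "
                         f"got shape {stack.shape}")
    if frame_rate is None:
        if meta and "fps" in meta:
            frame_rate = float(meta["fps"])
        elif meta and meta.get("finterval"):
            frame_rate = 1.0 / float(meta["finterval"])
        else:
            raise ValueError(f"{path}: no frame-rate metadata; pass frame_rate "
                             "or set frame_rate_fallback in the config")
    return np.asarray(stack), float(frame_rate)


# ---------------------------------------------------------------------------
# ROI archives

def read_roiset(path: str | Path, grid: tuple[int, int],
                labels: Optional[Dict[str, str]] = None,
                require_reference: bool = False) -> RoiSet:
    """Read an ImageJ ROI zip and rasterize each outline onto ``grid``.

    ``labels`` maps ROI entry names to region labels; entries without a
    mapping keep their own name. With ``require_reference`` the archive must
    contain exactly one ROI mapped to ``Reference``.
    """
    polys = imagej_roi.read_roi_zip(path)
    masks = {name: imagej_roi.rasterize_polygon(v, grid)
             for name, v in polys.items()}
    rs = RoiSet(masks=masks, labels=dict(labels or {}))
    if require_reference:
        rs.reference_name()
    return rs


def write_roiset_zip(path: str | Path,
                     polygons: Dict[str, np.ndarray]) -> None:
    imagej_roi.write_roi_zip(path, polygons)


# ---------------------------------------------------------------------------
# Trace tables (CSV / HDF5)

def write_recording_csv(path: str | Path, rec: Recording) -> None:
    """One column per channel plus a ``time_s`` column (relative to record
    start); sampling metadata goes in a ``# key: value`` comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sampling_rate: {rec.sampling_rate!r}\n")
        fh.write(f"# t_injection: {rec.t_injection!r}\n")
        fh.write(f"# injection_duration: {rec.injection_duration!r}\n")
        fh.write(f"# modality: {rec.modality}\n")
        data = rec.samples if rec.samples.ndim == 2 else rec.samples[None]
        roles = {i: f"ch{i}" for i in range(data.shape[0])}
        for role, idx in (rec.channel_roles or {}).items():
            roles[idx] = role
        t = np.arange(data.shape[1]) / rec.sampling_rate
        df = pd.DataFrame({"time_s": t})
        for i in range(data.shape[0]):
            df[roles[i]] = data[i]
        df.to_csv(fh, index=False)


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    meta: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    channels = [c for c in df.columns if c != "time_s"]
    data = df[channels].to_numpy().T
    roles = {name: i for i, name in enumerate(channels)}
    if data.shape[0] == 1:
        data = data[0]
        roles = None if channels == ["ch0"] else {channels[0]: 0}
    return Recording(
        samples=data,
        sampling_rate=float(meta["sampling_rate"]),
        t_injection=float(meta["t_injection"]),
        injection_duration=float(meta.get("injection_duration", 8.0)),
        modality=meta.get("modality", "photometry"),
        channel_roles=roles,
    )


def write_recording_h5(path: str | Path, rec: Recording) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("samples", data=rec.samples)
        ds.attrs["sampling_rate"] = rec.sampling_rate
        ds.attrs["t_injection"] = rec.t_injection
        ds.attrs["injection_duration"] = rec.injection_duration
        ds.attrs["modality"] = rec.modality
        if rec.channel_roles:
            for role, idx in rec.channel_roles.items():
                ds.attrs[f"role_{role}"] = idx


def read_recording_h5(path: str | Path) -> Recording:
    import h5py

    with h5py.File(path, "r") as h5:
        ds = h5["samples"]
        roles = {k[5:]: int(v) for k, v in ds.attrs.items()
                 if k.startswith("role_")}
        return Recording(
            samples=ds[()],
            sampling_rate=float(ds.attrs["sampling_rate"]),
            t_injection=float(ds.attrs["t_injection"]),
            injection_duration=float(ds.attrs.get("injection_duration", 8.0)),
            modality=str(ds.attrs.get("modality", "photometry")),
            channel_roles=roles or None,
        )


def read_recording(path: str | Path) -> Recording:
    """Dispatch on extension: ``.csv`` or ``.h5``/``.hdf5``."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_recording_csv(path)
    if suffix in (".h5", ".hdf5"):
        return read_recording_h5(path)
    raise ValueError(f"unsupported trace format {suffix!r}")


def write_cell_traces_csv(path: str | Path, traces: np.ndarray,
                          sampling_rate: float, t_injection: float,
                          animals: Optional[list] = None) -> None:
    """Per-cell trace matrix (cells × time) with an animal grouping column."""
    traces = np.asarray(traces, dtype=float)
    n_cells, n_t = traces.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sampling_rate: {sampling_rate!r}\n")
        fh.write(f"# t_injection: {t_injection!r}\n")
        df = pd.DataFrame(traces,
                          columns=[f"s{i}" for i in range(n_t)])
        df.insert(0, "cell", [f"cell{i}" for i in range(n_cells)])
        df.insert(1, "animal", animals if animals is not None
                  else ["animal0"] * n_cells)
        df.to_csv(fh, index=False)


def read_cell_traces_csv(path: str | Path
                         ) -> tuple[np.ndarray, float, float, pd.DataFrame]:
    """Returns (traces cells×time, sampling_rate, t_injection, id frame)."""
    meta: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    ids = df[["cell", "animal"]].copy()
    traces = df.drop(columns=["cell", "animal"]).to_numpy(dtype=float)
    return traces, float(meta["sampling_rate"]), float(meta["t_injection"]), ids


# ---------------------------------------------------------------------------
# Run manifests

def write_manifest(path: str | Path, config: RunConfig,
                   seed: Optional[int] = None, **extra) -> None:
    from . import __version__

    payload = {
        "gbsig_version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        **extra,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
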