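"""Tag-deployment data model, CSV readers/writers and pre-processing.

A deployment is a uniform multichannel time series recorded by an
animal-borne tag: depth (m, positive down, surface = 0), orientation
angles (rad), speed (m/s) and triaxial acceleration, all on a common
sampling grid.  Timestamps are seconds since deployment start (0-based).
Channel tables are plain CSV with unit-suffixed headers; lunge
annotations are a second CSV with one row per event.

Pre-processing mirrors standard tag practice: decimation to 10 Hz with an
anti-alias filter, and removal of the first hour of data after tag-on to
avoid the behavioural disturbance of tagging.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: Channel-table column names (unit suffixes are part of the dialect).
CHANNEL_COLUMNS = [
    "time_s",
    "depth_m",
    "pitch_rad",
    "roll_rad",
    "heading_rad",
    "speed_ms",
    "accel_x",
    "accel_y",
    "accel_z",
]


@dataclass
class TagDeployment:
    """Uniform multichannel record plus metadata for one whale.

    Attributes
    ----------
    id, species : str
        Deployment label and species label.
    fs : float
        Sampling rate in Hz; all channels share the grid ``time``.
    time, depth, pitch, roll, heading, speed : ndarray
        Channel vectors, all of equal length.  ``time`` is strictly
        increasing and uniform at 1/fs.
    accel : ndarray, shape (3, N)
        Triaxial acceleration (arbitrary consistent units; the breath
        detector only uses differenced values, so offsets are irrelevant).
    total_length : float or None
        Photogrammetric total length in metres, if known.
    """

    id: str
    species: str
    fs: float
    time: np.ndarray
    depth: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    heading: np.ndarray
    speed: np.ndarray
    accel: np.ndarray
    start_time: float = 0.0
    total_length: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        for name in ("depth", "pitch", "roll", "heading", "speed"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size != n:
                raise ValueError(f"channel {name!r} has {v.size} samples, expected {n}")
            setattr(self, name, v)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.shape != (3, n):
            raise ValueError(f"accel must have shape (3, {n}), got {self.accel.shape}")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing (duplicate or reversed timestamps)")
            # tolerate up to one sample of jitter against the nominal grid
            if np.any(np.abs(dt - 1.0 / self.fs) > 1.0 / self.fs):
                raise ValueError("timestamps deviate from a uniform 1/fs grid by more than one sample")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depth contains non-finite values")
        if np.any(np.abs(self.roll) > np.pi + 1e-9):
            raise ValueError("roll must lie in [-pi, pi]")
        if np.any((self.heading < -np.pi - 1e-9) | (self.heading >= np.pi + 1e-9)):
            raise ValueError("heading must lie in [-pi, pi)")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Record span in seconds (n/fs)."""
        return self.n_samples / self.fs


@dataclass
class AnnotationTable:
    """Event annotations (lunges) for one deployment, sorted by time."""

    events: pd.DataFrame  # columns: event_type, time_s

    def __post_init__(self) -> None:
        required = {"event_type", "time_s"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        self.events = self.events.sort_values("time_s").reset_index(drop=True)

    @property
    def times(self) -> np.ndarray:
        return self.events["time_s"].to_numpy(dtype=float)

    def filter_span(self, t0: float, t1: float) -> "AnnotationTable":
        ev = self.events[(self.events["time_s"] >= t0) & (self.events["time_s"] <= t1)]
        return AnnotationTable(ev.reset_index(drop=True))


def lunge_annotations(times) -> AnnotationTable:
    """Build an :class:`AnnotationTable` of lunge events from a time list."""
    return AnnotationTable(
        pd.DataFrame({"event_type": "lunge", "time_s": np.asarray(times, dtype=float)})
    )


def read_deployment(channel_file, metadata) -> TagDeployment:
    """Read a channel-table CSV plus metadata into a :class:`TagDeployment`.

    Parameters
    ----------
    channel_file : path
        CSV with the columns in :data:`CHANNEL_COLUMNS`.
    metadata : dict or path
        Mapping (or JSON file) with at least ``id``, ``species`` and
        ``fs``; optional ``total_length`` and ``start_time``.

    Rows with non-finite depth are rejected (their count is logged);
    missing columns and duplicated timestamps raise.
    """
    channel_file = Path(channel_file)
    if not channel_file.exists():
        raise FileNotFoundError(channel_file)
    if not isinstance(metadata, dict):
        metadata = json.loads(Path(metadata).read_text())
    df = pd.read_csv(channel_file)
    for col in CHANNEL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"channel file missing required column {col!r}")
    bad = ~np.isfinite(df["depth_m"].to_numpy(dtype=float))
    if bad.any():
        logger.warning("rejecting %d rows with non-finite depth", int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    t = df["time_s"].to_numpy(dtype=float)
    if np.unique(t).size != t.size:
        raise ValueError("duplicated timestamps in channel file")
    return TagDeployment(
        id=str(metadata["id"]),
        species=str(metadata["species"]),
        fs=float(metadata["fs"]),
        time=t,
        depth=df["depth_m"].to_numpy(dtype=float),
        pitch=df["pitch_rad"].to_numpy(dtype=float),
        roll=df["roll_rad"].to_numpy(dtype=float),
        heading=df["heading_rad"].to_numpy(dtype=float),
        speed=df["speed_ms"].to_numpy(dtype=float),
        accel=df[["accel_x", "accel_y", "accel_z"]].to_numpy(dtype=float).T,
        start_time=float(metadata.get("start_time", 0.0)),
        total_length=(
            float(metadata["total_length"]) if metadata.get("total_length") else None
        ),
    )


def write_deployment(dep: TagDeployment, channel_file, metadata_file=None) -> None:
    """Write the channel table (and optionally a JSON metadata sidecar)."""
    df = pd.DataFrame(
        {
            "time_s": dep.time,
            "depth_m": dep.depth,
            "pitch_rad": dep.pitch,
            "roll_rad": dep.roll,
            "heading_rad": dep.heading,
            "speed_ms": dep.speed,
            "accel_x": dep.accel[0],
            "accel_y": dep.accel[1],
            "accel_z": dep.accel[2],
        }
    )
    df.to_csv(channel_file, index=False)
    if metadata_file is not None:
        meta = {
            "id": dep.id,
            "species": dep.species,
            "fs": dep.fs,
            "start_time": dep.start_time,
            "total_length": dep.total_length,
            "duration_s": dep.duration,
        }
        Path(metadata_file).write_text(json.dumps(meta, indent=2) + "\n")


def _decimate_channel(x: np.ndarray, q: int) -> np.ndarray:
    # polyphase FIR resampling; line padding keeps constants constant and
    # avoids edge ringing
    return signal.resample_poly(x, up=1, down=q, padtype="line")


def _decimate_angle(x: np.ndarray, q: int) -> np.ndarray:
    # filter on the unwrapped angle, re-wrap afterwards: a wrapped jump at
    # +/-pi would otherwise ring through the anti-alias filter
    y = _decimate_channel(np.unwrap(x), q)
    return np.mod(y + np.pi, 2 * np.pi) - np.pi


def decimate_to_10hz(dep: TagDeployment) -> TagDeployment:
    """Anti-alias low-pass and downsample all channels to 10 Hz.

    The input rate must be an integer multiple of 10 Hz; a 10-Hz input is
    returned unchanged (copy).  Upsampling is refused.
    """
    if dep.fs < 10:
        raise ValueError(f"cannot decimate fs={dep.fs} Hz < 10 Hz (no upsampling)")
    if dep.fs == 10:
        return replace(dep)
    q = dep.fs / 10.0
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"fs={dep.fs} Hz is not an integer multiple of 10 Hz")
    q = int(round(q))
    dec = lambda x: _decimate_channel(x, q)
    n_out = math.ceil(dep.n_samples / q)
    time = dep.time[0] + np.arange(n_out) / 10.0
    return TagDeployment(
        id=dep.id,
        species=dep.species,
        fs=10.0,
        time=time,
        depth=dec(dep.depth),
        pitch=dec(dep.pitch),
        roll=_decimate_angle(dep.roll, q),
        heading=_decimate_angle(dep.heading, q),
        speed=dec(dep.speed),
        accel=np.vstack([dec(dep.accel[i]) for i in range(3)]),
        start_time=dep.start_time,
        total_length=dep.total_length,
    )


def trim_first_hour(dep: TagDeployment, annotations: AnnotationTable | None = None):
    """Drop the first hour of data following tag-on.

    All samples with ``t < 3600 s`` are removed (timestamps are kept
    absolute, so the trimmed record starts at t = 3600 s).  If an
    annotation table is given it is filtered to the retained span and a
    ``(deployment, annotations)`` tuple is returned.
    """
    if dep.duration <= 3600.0:
        raise ValueError(
            f"deployment {dep.id}: duration {dep.duration:.0f} s <= 1 h, unusable after first-hour trim"
        )
    keep = dep.time >= 3600.0
    out = TagDeployment(
        id=dep.id,
        species=dep.species,
        fs=dep.fs,
        time=dep.time[keep],
        depth=dep.depth[keep],
        pitch=dep.pitch[keep],
        roll=dep.roll[keep],
        heading=dep.heading[keep],
        speed=dep.speed[keep],
        accel=dep.accel[:, keep],
        start_time=dep.start_time,
        total_length=dep.total_length,
    )
    if annotations is None:
        return out
    return out, annotations.filter_span(out.time[0], out.time[-1] + 1.0 / out.fs)
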