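"""Reading/writing sensor and annotation files, and clock synchronization.

The sensor cannot timestamp wall-clock time; in the field the video shows a
timer started together with the sensor, and the annotation clock is mapped
onto the sensor clock by a single constant offset.  ``SyncSpec`` carries
that offset; no automatic estimator is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SLOT_S, AnnotationTrack, SensorTrace

__all__ = [
    "FormatError",
    "SamplingError",
    "SyncSpec",
    "read_sensor",
    "write_sensor",
    "read_annotations",
    "write_annotations",
    "apply_sync",
    "load_manifest",
    "load_session",
]

SENSOR_COLUMNS = ["t", "acc_x", "acc_y", "acc_z"]


class FormatError(ValueError):
    """The file does not have the expected columns/values."""


class SamplingError(ValueError):
    """The sensor stream is not uniformly sampled."""


@dataclass(frozen=True)
class SyncSpec:
    """Seconds to add to annotation times to land on the sensor clock."""

    offset_s: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.offset_s):
            raise ValueError("offset_s must be finite")


def write_sensor(trace: SensorTrace, path) -> None:
    df = pd.DataFrame(
        {
            "t": trace.t,
            "acc_x": trace.acc[:, 0],
            "acc_y": trace.acc[:, 1],
            "acc_z": trace.acc[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_sensor(path) -> SensorTrace:
    """Read a delimited sensor stream; extra columns (gyro, mag) are ignored.

    The sampling rate is inferred from the median sample spacing; spacing
    irregular beyond 1% of that interval is rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    if len(df) == 0:
        raise FormatError("empty trace")
    sub = df[SENSOR_COLUMNS]
    if sub.isna().any().any():
        raise FormatError("NaN samples in sensor stream")
    t = sub["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SamplingError("need at least two samples to infer the rate")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise SamplingError("non-increasing timestamps")
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise SamplingError("irregular sampling beyond 1% of the nominal interval")
    fs = 1.0 / med
    acc = sub[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    return SensorTrace(t=t, acc=acc, fs=fs)


def write_annotations(track: AnnotationTrack, path) -> None:
    pd.DataFrame({"slot_start": track.slot_start, "label": track.label}).to_csv(
        path, index=False
    )


def read_annotations(path) -> AnnotationTrack:
    df = pd.read_csv(path)
    missing = [c for c in ("slot_start", "label") if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    if len(df) == 0:
        raise FormatError("empty annotation track")
    return AnnotationTrack(
        slot_start=df["slot_start"].to_numpy(dtype=float),
        label=df["label"].to_numpy(dtype=int),
    )


def apply_sync(
    track: AnnotationTrack, sync: SyncSpec, trace: SensorTrace
) -> AnnotationTrack:
    """Shift the annotation clock onto the sensor clock and clip.

    Slots that are only partially covered by the sensor stream after the
    shift are dropped: a label must describe a full 0.5 s of signal.
    """
    eps = 1e-9
    shifted = track.slot_start + sync.offset_s
    lo, hi = trace.span
    keep = (shifted >= lo - eps) & (shifted + SLOT_S <= hi + eps)
    if not keep.any():
        raise ValueError("no overlap between annotations and sensor stream")
    return AnnotationTrack(slot_start=shifted[keep], label=track.label[keep])


def load_manifest(path) -> dict:
    """Flat key-value session manifest: sensor, annotation, offset_s."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict):
        raise FormatError("manifest must be a flat mapping")
    for key in ("sensor", "annotation"):
        if key not in manifest:
            raise FormatError(f"manifest missing key '{key}'")
    manifest.setdefault("offset_s", 0.0)
    return manifest


def load_session(manifest_path) -> tuple[SensorTrace, AnnotationTrack]:
    """Read the files named in a manifest and return the synced pair."""
    manifest = load_manifest(manifest_path)
    base = Path(manifest_path).parent
    trace = read_sensor(base / manifest["sensor"])
    track = read_annotations(base / manifest["annotation"])
    track = apply_sync(track, SyncSpec(float(manifest["offset_s"])), trace)
    return trace, track
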