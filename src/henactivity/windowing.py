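"""Overlapping fixed-length windows with majority-vote class labels.

The synchronized stream is cut into windows of 1 s or 4 s advanced by a
0.5-s shift (50% / 87.5% overlap).  Each window takes the majority label of
the 0.5-s annotation slots it spans; exact ties go to the higher class
index, protecting the rare highly dynamic class from erasure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .synthetic import SLOT_S, AnnotationTrack, SensorTrace

__all__ = ["WindowSpec", "LabeledWindow", "WindowSet", "make_windows", "majority_label"]


@dataclass(frozen=True)
class WindowSpec:
    window_s: float = 1.0
    shift_s: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.shift_s <= 0:
            raise ValueError("window_s and shift_s must be positive")
        ratio = self.window_s / self.shift_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("window_s must be an integer multiple of shift_s")

    @property
    def overlap(self) -> float:
        """Overlap fraction between consecutive windows."""
        return 1.0 - self.shift_s / self.window_s

    def n_samples(self, fs: float) -> int:
        n = self.window_s * fs
        if abs(n - round(n)) > 1e-6:
            raise ValueError("window_s x fs must be an integer sample count")
        return int(round(n))


@dataclass
class LabeledWindow:
    start_s: float
    samples: np.ndarray  #: (window_s * fs, 3) m/s^2
    label: int


class WindowSet(Sequence):
    """All windows of one session, stored as one (n, w, 3) array.

    Behaves as a sequence of :class:`LabeledWindow` but keeps the samples
    in a single strided block so feature extraction can be vectorized.
    """

    def __init__(self, starts: np.ndarray, samples: np.ndarray, labels: np.ndarray):
        self.starts = np.asarray(starts, dtype=float)
        self.samples = samples
        self.labels = np.asarray(labels, dtype=int)
        if not (len(self.starts) == len(self.samples) == len(self.labels)):
            raise ValueError("starts, samples and labels must have equal length")

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return WindowSet(self.starts[i], self.samples[i], self.labels[i])
        return LabeledWindow(
            start_s=float(self.starts[i]),
            samples=np.asarray(self.samples[i]),
            label=int(self.labels[i]),
        )

    def __iter__(self) -> Iterator[LabeledWindow]:
        for i in range(len(self)):
            yield self[i]


def majority_label(slot_labels) -> int:
    """Most frequent label; ties go to the highest class index."""
    labels = np.asarray(slot_labels, dtype=int)
    if labels.size == 0:
        raise ValueError("cannot take the majority of an empty label list")
    if not np.isin(labels, (1, 2, 3)).all():
        raise ValueError("labels must be in {1, 2, 3}")
    counts = np.array([(labels == c).sum() for c in (1, 2, 3)])
    return int(3 - np.argmax(counts[::-1]))


def make_windows(
    trace: SensorTrace, track: AnnotationTrack, spec: WindowSpec
) -> WindowSet:
    """Cut the aligned stream into labelled windows.

    Windows start on the annotation slot grid at the first instant fully
    covered by both the sensor stream and the annotation track, advance by
    ``shift_s`` and are emitted only while fully covered by both.  A
    covered duration shorter than the window yields an empty set.
    """
    eps = 1e-9
    fs = trace.fs
    w_n = spec.n_samples(fs)
    shift_n = int(round(spec.shift_s * fs))
    if shift_n == 0 or abs(spec.shift_s * fs - shift_n) > 1e-6:
        raise ValueError("shift_s x fs must be an integer sample count")
    # labels live on the 0.5-s slot grid, so window geometry must respect it
    for name, value in (("window_s", spec.window_s), ("shift_s", spec.shift_s)):
        if abs(value / SLOT_S - round(value / SLOT_S)) > 1e-9:
            raise ValueError(f"{name} must be a multiple of the 0.5-s slot length")

    trace_lo, trace_hi = trace.span
    track_lo, track_hi = track.span
    # anchor on the slot grid: first slot start covered by the trace
    k0 = int(np.ceil((trace_lo - track_lo - eps) / SLOT_S))
    t0 = track_lo + max(k0, 0) * SLOT_S
    cov_end = min(trace_hi, track_hi)
    covered = cov_end - t0
    if covered + eps < spec.window_s:
        return WindowSet(np.empty(0), np.empty((0, w_n, 3)), np.empty(0, dtype=int))

    n_windows = int(np.floor((covered - spec.window_s) / spec.shift_s + eps)) + 1
    starts = t0 + np.arange(n_windows) * spec.shift_s

    # sample block per window, via one strided view over the trace
    i0 = int(round((t0 - trace.t[0]) * fs))
    view = np.lib.stride_tricks.sliding_window_view(trace.acc, w_n, axis=0)
    idx = i0 + np.arange(n_windows) * shift_n
    samples = np.moveaxis(view[idx], 1, 2)  # (n, w_n, 3)

    # majority label over the 0.5-s slots each window spans
    slots_per_win = int(round(spec.window_s / SLOT_S))
    s0 = int(round((t0 - track_lo) / SLOT_S))
    slot_step = spec.shift_s / SLOT_S
    slot_idx = s0 + np.rint(
        np.arange(n_windows)[:, None] * slot_step + np.arange(slots_per_win)[None, :]
    ).astype(int)
    win_slots = track.label[slot_idx]
    counts = np.stack([(win_slots == c).sum(axis=1) for c in (1, 2, 3)], axis=1)
    labels = 3 - np.argmax(counts[:, ::-1], axis=1)

    return WindowSet(starts, samples, labels)
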