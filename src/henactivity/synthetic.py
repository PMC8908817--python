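"""Synthetic annotated hen-accelerometer sessions.

Real recordings of backpack-mounted IMUs on laying hens are rarely shared,
so the pipeline ships a generator that emulates the statistical structure
such a session has: long static stretches (resting, perching), rhythmic
moderate-intensity activity (preening, foraging), and rare, very short
high-intensity events (wing flapping, the shaking phase of dust bathing)
that appear as sharp spikes in the acceleration signal.

The hidden behaviour sequence is a semi-Markov bout process: bout classes
are drawn i.i.d. with entry probabilities chosen so that the long-run
fraction of time spent in class ``i`` equals ``class_probs[i]``, and bout
durations are exponential with per-class means.  On top of the class
sequence a simple per-class signal model is rendered at ``fs`` Hz:

* class 1 (static): gravity offset on one axis plus white noise, with
  occasional brief low-amplitude postural shifts (a resting hen still
  moves its head and shoulders now and then),
* class 2 (semi-dynamic): class 1 plus a sinusoid with per-bout random
  phase, rate and amplitude jitter, gated by an activity envelope of
  bursts and pauses (foraging and preening are intermittent),
* class 3 (highly dynamic): class 1 plus short Gaussian-shaped transients
  recurring within the bout.

The postural shifts and activity pauses matter: they are what makes very
short windows genuinely ambiguous between the static and semi-dynamic
classes, while longer windows average over them.

An annotation track mirrors human video scoring: one behaviour label per
0.5-s slot, assigned by majority occupancy within the slot (ties broken
toward the higher, i.e. rarer and more dynamic, class).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimulationConfig",
    "SensorTrace",
    "AnnotationTrack",
    "PROFILES",
    "table3_profile",
    "simulate_session",
    "inject_label_noise",
]

SLOT_S = 0.5
GRAVITY = 9.81
CLASSES = (1, 2, 3)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated session.

    Defaults reproduce the committed ``table3`` profile: a ~2 h 20 min
    session at 100 Hz whose slot-label proportions match the severely
    imbalanced class census of the motivating field study
    (3023/3606/37 windows out of 6666).
    """

    duration_s: float = 8400.0
    fs: float = 100.0
    #: stationary slot-label proportions, classes 1..3
    class_probs: tuple[float, float, float] = (0.453, 0.541, 0.006)
    #: mean bout duration per class, seconds
    mean_bout_s: tuple[float, float, float] = (30.0, 30.0, 2.0)
    #: static-behaviour noise SD, m/s^2
    baseline_g: float = 0.05
    #: nominal amplitude of the semi-dynamic sinusoid, m/s^2
    class2_amp: float = 0.25
    class2_freq_hz: float = 2.5
    #: nominal spike amplitude of highly dynamic transients, m/s^2
    class3_peak_amp: float = 12.0
    #: Gaussian sigma of a transient, seconds
    class3_peak_width_s: float = 0.08
    #: mean transient recurrence rate within a class-3 bout, Hz
    class3_peak_rate_hz: float = 2.5
    #: additive sensor white-noise SD, m/s^2
    sensor_noise_sd: float = 0.03
    #: axis index carrying the constant gravity offset
    gravity_axis: int = 2
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.class_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("class_probs must be 3 non-negative values summing to 1")
        if not np.any(p > 0):
            raise ValueError("at least one class probability must be positive")
        if not (self.class3_peak_amp > self.class2_amp > self.baseline_g):
            raise ValueError(
                "amplitude ordering class3_peak_amp > class2_amp > baseline_g required"
            )
        if not self.mean_bout_s[2] < 4.0:
            raise ValueError("class-3 mean bout must be shorter than the 4-s window")
        if self.duration_s < SLOT_S:
            raise ValueError("session too short")
        if self.fs <= 0 or min(self.mean_bout_s) <= 0:
            raise ValueError("fs and mean bout durations must be positive")
        if self.gravity_axis not in (0, 1, 2):
            raise ValueError("gravity_axis must be 0, 1 or 2")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def table3_profile(**overrides) -> SimulationConfig:
    """The committed default profile (imbalance as in the field census)."""
    return SimulationConfig(**overrides)


PROFILES = {"table3": table3_profile}


@dataclass
class SensorTrace:
    """Uniformly sampled tri-axial acceleration stream."""

    t: np.ndarray  #: sample times, seconds
    acc: np.ndarray  #: (n, 3) acceleration, m/s^2
    fs: float  #: sampling rate, Hz

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.t.ndim != 1 or self.acc.shape != (self.t.size, 3):
            raise ValueError("trace needs 1-d t and matching (n, 3) acc")
        if self.t.size and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if not np.all(np.isfinite(self.acc)):
            raise ValueError("acceleration must be finite")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def span(self) -> tuple[float, float]:
        """Covered time interval [start, end): the last sample covers 1/fs."""
        return float(self.t[0]), float(self.t[-1] + 1.0 / self.fs)


@dataclass
class AnnotationTrack:
    """Contiguous 0.5-s behaviour slots with class labels in {1, 2, 3}."""

    slot_start: np.ndarray  #: slot start times, seconds
    label: np.ndarray  #: per-slot class labels

    def __post_init__(self) -> None:
        self.slot_start = np.asarray(self.slot_start, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        if self.slot_start.shape != self.label.shape or self.slot_start.ndim != 1:
            raise ValueError("slot_start and label must be matching 1-d arrays")
        if self.slot_start.size > 1 and not np.allclose(
            np.diff(self.slot_start), SLOT_S, atol=1e-6
        ):
            raise ValueError("slots must be contiguous 0.5-s intervals")
        if self.label.size and not np.isin(self.label, CLASSES).all():
            raise ValueError("labels must be in {1, 2, 3}")

    @property
    def n_slots(self) -> int:
        return self.slot_start.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.slot_start[0]), float(self.slot_start[-1] + SLOT_S)


def _bout_sequence(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw (labels, durations) of bouts covering the session.

    Entry probabilities are proportional to class_probs / mean_bout so the
    long-run occupancy of class i converges to class_probs[i].
    """
    p = np.asarray(cfg.class_probs, dtype=float)
    m = np.asarray(cfg.mean_bout_s, dtype=float)
    q = np.where(p > 0, p / m, 0.0)
    q = q / q.sum()
    labels, durations, total = [], [], 0.0
    while total < cfg.duration_s:
        c = int(rng.choice(3, p=q)) + 1
        d = float(rng.exponential(m[c - 1]))
        d = max(d, 1.0 / cfg.fs)  # a bout spans at least one sample
        labels.append(c)
        durations.append(d)
        total += d
    return np.array(labels), np.array(durations)


def _burst_envelope(
    rng: np.random.Generator,
    n: int,
    fs: float,
    active_mean_s: float,
    pause_mean_s: float,
) -> np.ndarray:
    """0/1 activity gate: exponential active bursts separated by pauses."""
    env = np.ones(n)
    pos = 0
    active = True
    while pos < n:
        mean = active_mean_s if active else pause_mean_s
        seg = max(int(rng.exponential(mean) * fs), 1)
        if not active:
            env[pos : pos + seg] = 0.0
        pos += seg
        active = not active
    return env


def simulate_session(config: SimulationConfig) -> tuple[SensorTrace, AnnotationTrack]:
    """Generate one annotated session. Identical seed, identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    bout_labels, bout_durs = _bout_sequence(config, rng)
    bout_ends = np.cumsum(bout_durs)
    bout_starts = bout_ends - bout_durs
    # per-sample hidden class
    sample_class = bout_labels[np.searchsorted(bout_ends, t, side="right")]

    acc = rng.normal(0.0, config.baseline_g, size=(n, 3))
    acc[:, config.gravity_axis] += GRAVITY

    sigma = config.class3_peak_width_s
    for c, b0, b1 in zip(bout_labels, bout_starts, bout_ends):
        if b0 >= config.duration_s:
            break
        i0, i1 = int(np.ceil(b0 * fs)), min(int(np.ceil(b1 * fs)), n)
        if i1 <= i0:
            continue
        if c == 1:
            # brief postural shifts: a low-frequency half-sine wobble a few
            # times a minute, amplitude a small multiple of the noise floor
            dur = b1 - b0
            n_shifts = rng.poisson(0.08 * dur)
            for ts in np.sort(rng.uniform(b0, b1, size=n_shifts)):
                sdur = rng.uniform(0.3, 0.8)
                j0 = max(int(ts * fs), i0)
                j1 = min(int((ts + sdur) * fs) + 1, i1)
                if j1 <= j0:
                    continue
                envelope = np.sin(np.pi * (t[j0:j1] - ts) / sdur).clip(min=0.0)
                amps = config.baseline_g * rng.uniform(2.0, 5.0, size=3)
                wob = np.sin(2 * np.pi * 1.5 * (t[j0:j1] - ts))
                acc[j0:j1] += (envelope * wob)[:, None] * amps[None, :]
        elif c == 2:
            # bouts differ in vigor: preening is gentler than foraging, so
            # amplitude and rhythm jitter per bout; the weakest bouts sit
            # close to the static noise floor, as in real recordings
            phases = rng.uniform(0.0, 2 * np.pi, size=3)
            amp = config.class2_amp * rng.uniform(0.1, 1.9)
            freq = config.class2_freq_hz * rng.uniform(0.6, 1.4)
            tt = t[i0:i1]
            burst = _burst_envelope(
                rng, i1 - i0, fs, active_mean_s=2.0, pause_mean_s=0.5
            )
            acc[i0:i1] += (amp * burst)[:, None] * np.sin(
                2 * np.pi * freq * tt[:, None] + phases[None, :]
            )
        elif c == 3:
            dur = b1 - b0
            n_peaks = rng.poisson(config.class3_peak_rate_hz * dur)
            if n_peaks == 0:
                peak_times = np.array([b0 + dur / 2.0])
            else:
                peak_times = b0 + rng.uniform(0.0, dur, size=n_peaks)
            # each event loads one dominant axis (a flap or shake is a
            # directed movement), with only weak cross-axis spill
            for tp in np.sort(peak_times):
                j0 = max(int((tp - 4 * sigma) * fs), i0)
                j1 = min(int((tp + 4 * sigma) * fs) + 1, i1)
                if j1 <= j0:
                    continue
                bump = np.exp(-0.5 * ((t[j0:j1] - tp) / sigma) ** 2)
                amps = config.class3_peak_amp * rng.uniform(0.05, 0.3, size=3)
                axis = rng.integers(3)
                amps[axis] = config.class3_peak_amp * rng.uniform(0.35, 1.5)
                amps *= rng.choice([-1.0, 1.0], size=3)
                acc[j0:j1] += bump[:, None] * amps[None, :]

    acc += rng.normal(0.0, config.sensor_noise_sd, size=(n, 3))

    # annotation: majority occupancy per 0.5-s slot, ties toward higher class
    slot_samples = int(round(SLOT_S * fs))
    n_slots = n // slot_samples
    per_slot = sample_class[: n_slots * slot_samples].reshape(n_slots, slot_samples)
    counts = np.stack([(per_slot == c).sum(axis=1) for c in CLASSES], axis=1)
    # argmax over reversed class order picks the highest class among ties
    slot_label = 3 - np.argmax(counts[:, ::-1], axis=1)
    slot_start = np.arange(n_slots) * SLOT_S

    trace = SensorTrace(t=t, acc=acc, fs=fs)
    track = AnnotationTrack(slot_start=slot_start, label=slot_label)
    return trace, track


def inject_label_noise(
    track: AnnotationTrack, flip_prob: float, seed: int
) -> AnnotationTrack:
    """Independently re-label each slot with a random *different* class.

    Emulates imprecise human annotation; ``flip_prob`` is the per-slot
    probability of a wrong label.
    """
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = track.label.copy()
    flip = rng.random(labels.size) < flip_prob
    # pick one of the two other classes uniformly
    offset = rng.integers(1, 3, size=labels.size)
    labels[flip] = (labels[flip] - 1 + offset[flip]) % 3 + 1
    return AnnotationTrack(slot_start=track.slot_start.copy(), label=labels)
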