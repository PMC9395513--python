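"""Fixation / saccade / blink parsing of 1 kHz gaze recordings.

Samples are classified with a velocity-acceleration scheme: a saccade is a
maximal run of samples whose angular velocity exceeds the velocity
threshold or whose angular acceleration exceeds the acceleration
threshold, provided the run's total displacement exceeds the motion
threshold; the complementary runs are fixations, and gaps in the signal
become blinks.  Velocity and acceleration are estimated by central
differences over a 5-sample window after light moving-average smoothing of
the positions — 1 kHz data need noise suppression before differentiation.

Default thresholds (30 deg/s, 8000 deg/s^2, 0.1 deg) are the tracker
defaults commonly used for cognitive experiments.  The pixel-to-degree
conversion defaults to the viewing geometry 29.3 deg across 1024 px
(~0.0286 deg/px) and is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import GazeRecording, GAP_THRESHOLD_MS

__all__ = [
    "EventThresholds",
    "Fixation",
    "Saccade",
    "Blink",
    "EventSequence",
    "px_to_deg",
    "detect_events",
    "filter_events",
    "subsample_events",
    "DEFAULT_DEG_PER_PX",
]

logger = logging.getLogger(__name__)

#: 29.3 degrees of visual angle across 1024 px at the 65 cm viewing distance.
DEFAULT_DEG_PER_PX = 29.3 / 1024

#: Duration filters applied before pooling eye-movement statistics.
MAX_FIXATION_MS = 1000.0
MAX_SACCADE_MS = 100.0


@dataclass(frozen=True)
class EventThresholds:
    """Detection thresholds; all strictly positive."""

    velocity_deg_s: float = 30.0
    acceleration_deg_s2: float = 8000.0
    motion_deg: float = 0.1
    deg_per_px: float = DEFAULT_DEG_PER_PX
    smoothing_window_ms: float = 11.0
    min_event_samples: int = 3  # anti-flicker: shorter runs merge into neighbours

    def __post_init__(self) -> None:
        for name in ("velocity_deg_s", "acceleration_deg_s2", "motion_deg",
                     "deg_per_px", "smoothing_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Fixation:
    onset: float  # ms
    offset: float  # ms
    cx: float  # centroid px
    cy: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Saccade:
    onset: float
    offset: float
    amplitude_deg: float
    peak_velocity_deg_s: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Blink:
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EventSequence:
    """Time-ordered, non-overlapping fixations, saccades and blinks."""

    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)
    blinks: list[Blink] = field(default_factory=list)

    def all_events(self) -> list:
        return sorted(self.fixations + self.saccades + self.blinks,
                      key=lambda e: e.onset)


def px_to_deg(d_px: float, thresholds: EventThresholds) -> float:
    """Convert a pixel distance to degrees of visual angle (small-angle)."""
    return d_px * thresholds.deg_per_px


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(a) < window:
        return a
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(a, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _central_diff(a: np.ndarray, t: np.ndarray, half: int = 2) -> np.ndarray:
    """d a / d t by central differences over +-``half`` samples, edge-padded."""
    n = len(a)
    out = np.empty(n)
    if n <= 2 * half:
        out[:] = np.gradient(a, t) if n > 1 else 0.0
        return out
    out[half:-half] = (a[2 * half:] - a[:-2 * half]) / (t[2 * half:] - t[:-2 * half])
    out[:half] = out[half]
    out[-half:] = out[-half - 1]
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    edges = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    return list(zip(edges[::2], edges[1::2]))


def _label_segment(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                   thr: EventThresholds) -> np.ndarray:
    """Saccade mask and speed profile for one gap-free run of valid samples."""
    dt_ms = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    window = max(1, int(round(thr.smoothing_window_ms / dt_ms)) | 1)
    xs, ys = _smooth(x, window), _smooth(y, window)
    vx = _central_diff(xs, t)  # px/ms
    vy = _central_diff(ys, t)
    speed = np.hypot(vx, vy) * thr.deg_per_px * 1000.0  # deg/s
    acc = _central_diff(speed, t) * 1000.0  # deg/s^2
    is_sac = (speed > thr.velocity_deg_s) | (np.abs(acc) > thr.acceleration_deg_s2)

    # motion criterion: a saccade run must displace gaze by > motion_deg
    for s, e in _runs(is_sac):
        disp = math.hypot(xs[e - 1] - xs[s], ys[e - 1] - ys[s]) * thr.deg_per_px
        if disp <= thr.motion_deg:
            is_sac[s:e] = False

    # anti-flicker: absorb runs shorter than min_event_samples into neighbours
    changed = True
    while changed:
        changed = False
        for mask in (is_sac, ~is_sac):
            for s, e in _runs(mask):
                if e - s < thr.min_event_samples and not (s == 0 and e == len(t)):
                    is_sac[s:e] = not is_sac[s]
                    changed = True
                    break
            if changed:
                break
    return is_sac, speed


def detect_events(gaze: GazeRecording, thresholds: EventThresholds | None = None,
                  ) -> EventSequence:
    """Parse a gaze recording into fixations, saccades and blinks.

    Contiguous valid runs are classified independently; gaps between them
    longer than the blink threshold become blink events.  An all-invalid
    recording yields an empty sequence with a warning.
    """
    thr = thresholds or EventThresholds()
    seq = EventSequence()
    if len(gaze) == 0 or not np.any(gaze.valid):
        logger.warning("no valid gaze samples; returning empty event sequence")
        return seq

    for t0, t1 in gaze.gaps():
        seq.blinks.append(Blink(onset=t0, offset=t1))

    # contiguous valid runs, further split at holes in the time grid
    segments: list[np.ndarray] = []
    for s, e in _runs(gaze.valid):
        idx = np.arange(s, e)
        holes = np.flatnonzero(np.diff(gaze.t[idx]) > GAP_THRESHOLD_MS)
        segments.extend(np.split(idx, holes + 1))
    for idx in segments:
        if idx.size < 2:
            continue
        t, x, y = gaze.t[idx], gaze.x[idx], gaze.y[idx]
        is_sac, speed = _label_segment(t, x, y, thr)
        for s, e in _runs(is_sac):
            amp = math.hypot(x[e - 1] - x[s], y[e - 1] - y[s]) * thr.deg_per_px
            seq.saccades.append(Saccade(onset=float(t[s]), offset=float(t[e - 1]),
                                        amplitude_deg=amp,
                                        peak_velocity_deg_s=float(speed[s:e].max())))
        for s, e in _runs(~is_sac):
            seq.fixations.append(Fixation(onset=float(t[s]), offset=float(t[e - 1]),
                                          cx=float(x[s:e].mean()),
                                          cy=float(y[s:e].mean())))
    seq.fixations.sort(key=lambda f: f.onset)
    seq.saccades.sort(key=lambda s: s.onset)
    seq.blinks.sort(key=lambda b: b.onset)
    return seq


def filter_events(events: EventSequence,
                  max_fixation_ms: float = MAX_FIXATION_MS,
                  max_saccade_ms: float = MAX_SACCADE_MS) -> EventSequence:
    """Drop over-long events: fixations > 1000 ms and saccades > 100 ms."""
    fixations = [f for f in events.fixations if f.duration <= max_fixation_ms]
    saccades = [s for s in events.saccades if s.duration <= max_saccade_ms]
    n_f = len(events.fixations) - len(fixations)
    n_s = len(events.saccades) - len(saccades)
    if n_f or n_s:
        logger.info("filter_events removed %d fixations, %d saccades", n_f, n_s)
    return EventSequence(fixations=fixations, saccades=saccades,
                         blinks=list(events.blinks))


def subsample_events(items, factor: int, seed: int):
    """Uniform random subsample of size ceil(N / factor), seed-deterministic.

    Used to equilibrate pooled duration samples before distribution tests
    (subsampling "by an order of magnitude" means factor 10).  Factor
    larger than N keeps a single element with a warning.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    items = list(items)
    if factor == 1:
        return items
    n = len(items)
    k = max(1, math.ceil(n / factor))
    if factor > n:
        logger.warning("subsample factor %d exceeds N=%d; keeping one element",
                       factor, n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return [items[i] for i in idx]
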