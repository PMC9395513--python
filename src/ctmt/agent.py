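"""Synthetic eye-hand agent: simulates complete cTMT sessions with ground truth.

The agent is a *generator of statistically plausible scanpaths and cursor
paths*, not a model of human strategy.  Per trial it performs a few
exploratory fixations, then works through the trail: targets whose
locations are still within its memory span (the most recently
fixated-but-unreached items) are reached directly without a preceding
re-fixation — these are the ground-truth "remembered" targets — while
forgotten targets require search fixations, the last of which lingers on
the target while the hand sets off (the re-fixation-before-reach case).
Search fixations that land on non-next items are false detections; with a
configurable probability the hand transiently drifts toward the falsely
detected item, covering a configurable fraction of the distance, before
correcting course — the substrate of the inhibition metric.

Gaze is rendered at 1 kHz with white positional noise; saccades use a
symmetric (triangular-velocity) profile scaled to the peak-velocity
parameter.  The mouse is logged only while it moves, matching the
irregular-sampling semantics of the readers.  All stochasticity flows
from a single seed through numpy SeedSequence spawning.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .events import DEFAULT_DEG_PER_PX
from .io import GazeRecording, MouseTrajectory, write_gaze, write_mouse
from .stimuli import GridSpec, StimulusLayout, assign_labels, generate_layout_set

__all__ = [
    "AgentParameters",
    "ScheduledFixation",
    "TrialTruth",
    "SimulatedTrial",
    "SimulatedSession",
    "simulate_trial",
    "simulate_session",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class AgentParameters:
    """Behavioural knobs of the simulated participant."""

    memory_span: int = 3  # target locations retained from prior fixations
    fixation_shape: float = 4.0  # gamma shape of fixation durations
    fixation_scale_ms: float = 50.0  # gamma scale (mean = shape * scale)
    saccade_peak_velocity_deg_s: float = 300.0
    hand_speed_px_s: float = 600.0
    false_drift_prob: float = 0.3  # P(hand orients toward a false detection)
    false_drift_gain: float = 0.35  # fraction of the item distance covered
    gaze_noise_deg: float = 0.03  # white positional noise, sd
    exploration_fixations: int = 3  # fixations before the first hand movement
    search_accuracy: float = 0.6  # P(a search fixation finds the next target)
    deg_per_px: float = DEFAULT_DEG_PER_PX
    trial_limit_s: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.false_drift_prob <= 1.0:
            raise ValueError("false_drift_prob must be in [0, 1]")
        if self.hand_speed_px_s <= 0:
            raise ValueError("hand_speed_px_s must be positive "
                             "(a motionless hand never finishes a trial)")
        if self.memory_span < 0 or self.exploration_fixations < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 < self.search_accuracy <= 1.0:
            raise ValueError("search_accuracy must be in (0, 1]")


@dataclass(frozen=True)
class ScheduledFixation:
    """Ground-truth fixation: where the agent meant to look."""

    onset: float
    offset: float
    x: float
    y: float
    item: int | None
    kind: str  # "correct" | "false" | None-item "scene"


@dataclass
class TrialTruth:
    fixations: list[ScheduledFixation] = field(default_factory=list)
    remembered: list[int] = field(default_factory=list)  # reached from memory
    reached: list[tuple[int, float]] = field(default_factory=list)  # (item, t)
    first_move_ms: float | None = None


@dataclass
class SimulatedTrial:
    layout: StimulusLayout
    gaze: GazeRecording
    mouse: MouseTrajectory
    truth: TrialTruth
    trial_type: str
    block: int


@dataclass
class SimulatedSession:
    participant: str
    params: AgentParameters
    trials: list[SimulatedTrial]


# ---------------------------------------------------------------------------
# internal scheduling machinery
# ---------------------------------------------------------------------------

_SCREEN_CENTRE = (300.0, 300.0)


def _fix_duration(params: AgentParameters, rng: np.random.Generator) -> float:
    d = rng.gamma(params.fixation_shape, params.fixation_scale_ms)
    return float(np.clip(d, 80.0, 900.0))


def _saccade_duration(dist_px: float, params: AgentParameters) -> float:
    amp = dist_px * params.deg_per_px
    return max(8.0, 2.0 * amp / params.saccade_peak_velocity_deg_s * 1000.0)


#: legs must keep this distance from non-endpoint item centres so the
#: cursor never clips a circle it is not meant to enter (reach radius 10)
_ITEM_CLEARANCE = 13.0


def _cross_z(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of the 2-D cross product (vectorised)."""
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def _points_seg_dist(P: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise distance from points P to segments (A, B); all (n, 2)."""
    D = B - A
    L2 = (D * D).sum(axis=1)
    safe = np.where(L2 > 0, L2, 1.0)
    u = np.clip(((P - A) * D).sum(axis=1) / safe, 0.0, 1.0)
    proj = A + u[:, None] * D
    return np.hypot(*(P - proj).T)


def _seg_seg_distances(a: np.ndarray, b: np.ndarray,
                       P0: np.ndarray, P1: np.ndarray) -> np.ndarray:
    """Distance from segment ab to each segment (P0[i], P1[i]); 0 if crossing."""
    D = P1 - P0
    e = b - a
    d1 = _cross_z(D, a - P0)
    d2 = _cross_z(D, b - P0)
    d3 = _cross_z(np.broadcast_to(e, D.shape), P0 - a)
    d4 = _cross_z(np.broadcast_to(e, D.shape), P1 - a)
    proper = (d1 * d2 < 0) & (d3 * d4 < 0)
    n = len(P0)
    A = np.broadcast_to(a, (n, 2))
    B = np.broadcast_to(b, (n, 2))
    dmin = np.minimum.reduce([
        _points_seg_dist(A, P0, P1), _points_seg_dist(B, P0, P1),
        _points_seg_dist(P0, A, B), _points_seg_dist(P1, A, B)])
    return np.where(proper, 0.0, dmin)


class _TrialBuilder:
    """Accumulates the gaze/hand schedule while the agent acts."""

    def __init__(self, layout: StimulusLayout, params: AgentParameters,
                 rng: np.random.Generator):
        self.layout = layout
        self.params = params
        self.rng = rng
        self.centres = np.asarray(layout.positions, float)
        self.t_gaze = 0.0
        self.gaze_pos = np.array(_SCREEN_CENTRE)
        self.hand_pos = np.array(_SCREEN_CENTRE)
        self.t_hand_free = 0.0
        self.hand_legs: list[tuple[float, float, np.ndarray, np.ndarray]] = []
        self.gaze_segments: list[tuple] = []  # ("fix"/"sac", t0, t1, p0, p1)
        self.truth = TrialTruth()
        self.seen: list[int] = []  # fixated-but-unreached, oldest first
        self.reached: set[int] = set()
        self.next_target = 0
        self.gaze_item: int | None = None  # currently fixated item
        self.limit_ms = params.trial_limit_s * 1000.0
        self._legs_cache: tuple[np.ndarray, np.ndarray] | None = None
        self._legs_cache_n = -1

    # -- gaze ------------------------------------------------------------
    def fixate(self, pos: np.ndarray, item: int | None,
               duration: float | None = None) -> tuple[float, float]:
        """Saccade to ``pos`` then fixate; returns (onset, offset)."""
        dist = float(np.hypot(*(pos - self.gaze_pos)))
        if dist > 1e-6:
            sd = _saccade_duration(dist, self.params)
            self.gaze_segments.append(("sac", self.t_gaze, self.t_gaze + sd,
                                       self.gaze_pos.copy(), pos.copy()))
            self.t_gaze += sd
        dur = duration if duration is not None else _fix_duration(self.params, self.rng)
        onset, offset = self.t_gaze, self.t_gaze + dur
        self.gaze_segments.append(("fix", onset, offset, pos.copy(), pos.copy()))
        self.t_gaze = offset
        self.gaze_pos = pos.copy()
        self.gaze_item = item
        if item is not None:
            kind = "correct" if item == self.next_target else "false"
            if item not in self.reached:
                if item in self.seen:
                    self.seen.remove(item)
                self.seen.append(item)
        else:
            kind = "scene"
        self.truth.fixations.append(ScheduledFixation(
            onset=onset, offset=offset, x=float(pos[0]), y=float(pos[1]),
            item=item, kind=kind))
        return onset, offset

    # -- hand ------------------------------------------------------------
    def hand_move(self, start_t: float, dest: np.ndarray,
                  avoid: bool = True) -> float:
        """Schedule a hand move beginning at ``start_t``; returns arrival time."""
        start_t = max(start_t, self.t_hand_free)
        a = self.hand_pos.copy()
        b = np.asarray(dest, float)
        pts = self._route_leg(a, b, [a], depth=5) if avoid else [a, b]
        t = start_t
        for a, b in zip(pts[:-1], pts[1:]):
            a = np.asarray(a, float)
            b = np.asarray(b, float)
            leg = float(np.hypot(*(b - a))) / self.params.hand_speed_px_s * 1000.0
            if leg > 0:
                self.hand_legs.append((t, t + leg, a, b))
                t += leg
        if self.truth.first_move_ms is None and t > start_t:
            self.truth.first_move_ms = start_t
        self.hand_pos = np.asarray(dest, float).copy()
        self.t_hand_free = t
        return t

    def _seg_violation(self, a: np.ndarray, b: np.ndarray,
                       route: list[np.ndarray]):
        """First obstacle segment a->b runs into, or None.

        Obstacles are earlier hand legs (which the trajectory must not
        cross — the drawn curve has to stay simple) and the reach circles
        of items other than the leg's own endpoints (which the cursor
        must not clip out of order).
        """
        n_legs = len(self.hand_legs)
        if self._legs_cache is None or self._legs_cache_n != n_legs:
            if n_legs:
                self._legs_cache = (
                    np.array([lg[2] for lg in self.hand_legs]),
                    np.array([lg[3] for lg in self.hand_legs]))
            else:
                self._legs_cache = (np.empty((0, 2)), np.empty((0, 2)))
            self._legs_cache_n = n_legs
        P0, P1 = self._legs_cache
        if len(route) > 1:
            P0 = np.concatenate([P0, np.asarray(route[:-1], float)])
            P1 = np.concatenate([P1, np.asarray(route[1:], float)])
        if len(P0):
            # skip legs sharing an endpoint with this one (departing/arriving)
            keep = ~(((np.abs(P1 - a) < 1e-9).sum(axis=1) == 2)
                     | ((np.abs(P0 - b) < 1e-9).sum(axis=1) == 2))
            if keep.any():
                P0k, P1k = P0[keep], P1[keep]
                # keep a margin: touching counts as a violation too (the
                # drawn curve must stay simple; tangency breaks simplicity)
                dist = _seg_seg_distances(a, b, P0k, P1k)
                bad = np.flatnonzero(dist < 2.0)
                if bad.size:
                    i = int(bad[0])
                    return ("leg", P0k[i], P1k[i])
        d = b - a
        L2 = float(d @ d)
        if L2 > 0:
            c = self.centres
            endpoint = (np.hypot(*(a - c).T) < _ITEM_CLEARANCE) \
                | (np.hypot(*(b - c).T) < _ITEM_CLEARANCE)
            u = np.clip((c - a) @ d / L2, 0.0, 1.0)
            foot = a + u[:, None] * d
            hit = (np.hypot(*(c - foot).T) < _ITEM_CLEARANCE) & ~endpoint
            bad = np.flatnonzero(hit)
            if bad.size:
                i = int(bad[0])
                return ("circle", c[i], foot[i])
        return None

    def _route_leg(self, a: np.ndarray, b: np.ndarray,
                   route: list[np.ndarray], depth: int = 5) -> list[np.ndarray]:
        """Best-effort obstacle-free polyline a->b (earlier legs + circles)."""
        viol = self._seg_violation(a, b, route)
        if viol is None or depth == 0:
            return [a, b]
        if viol[0] == "leg":
            _, p0, p1 = viol
            d = p1 - p0
            n = float(np.hypot(*d))
            if n < 1e-9:
                return [a, b]
            u = d / n
            perp = np.array([-u[1], u[0]])
            cands = [p0 - u * 18.0, p1 + u * 18.0,
                     p0 - u * 18.0 + perp * 18.0, p0 - u * 18.0 - perp * 18.0,
                     p1 + u * 18.0 + perp * 18.0, p1 + u * 18.0 - perp * 18.0,
                     p0 - u * 40.0, p1 + u * 40.0,
                     p0 - u * 40.0 + perp * 40.0, p0 - u * 40.0 - perp * 40.0,
                     p1 + u * 40.0 + perp * 40.0, p1 + u * 40.0 - perp * 40.0]
        else:
            _, c, foot = viol
            away = foot - c
            n = float(np.hypot(*away))
            if n < 1e-9:
                d = b - a
                away = np.array([-d[1], d[0]])
                n = float(np.hypot(*away)) or 1.0
            cands = [c + away / n * (_ITEM_CLEARANCE + 7.0),
                     c - away / n * (_ITEM_CLEARANCE + 7.0)]
        for w in cands:
            if self._seg_violation(a, w, route) is not None:
                continue
            tail = self._route_leg(w, b, route + [w], depth - 1)
            ok = all(self._seg_violation(s, e, route + [w]) is None
                     for s, e in zip(tail[:-1], tail[1:]))
            if ok:
                return [a] + tail
        return [a, b]  # no clean detour found: accept the violation

    # -- behaviour -------------------------------------------------------
    def _unreached_other(self, k: int) -> int | None:
        cand = [j for j in range(len(self.centres))
                if j not in self.reached and j != k and j != self.gaze_item]
        if not cand:
            return None
        # nearest-unvisited with randomised inspection order
        d = np.array([np.hypot(*(self.centres[j] - self.gaze_pos)) for j in cand])
        order = np.argsort(d)
        pick = order[min(int(self.rng.integers(0, min(3, len(order)))), len(order) - 1)]
        return cand[int(pick)]

    def _crosses_existing(self, a: np.ndarray, b: np.ndarray) -> bool:
        """Would segment a->b run into any earlier leg or foreign circle?"""
        return self._seg_violation(a, b, [a]) is not None

    def _maybe_drift(self, item: int, onset: float, offset: float) -> None:
        """Transient hand excursion toward a falsely detected item.

        The hand sets off toward the item shortly after the fixation
        lands on it, covers ``false_drift_gain`` of the distance, then
        corrects: it returns to a point a couple of pixels beside the
        anchor, so the trail does not retrace itself.  Drifting is
        skipped when the hand is travelling or when either excursion leg
        would run into an earlier leg — the drawn curve has to stay
        simple on correct trials.
        """
        p = self.params
        if self.rng.random() >= p.false_drift_prob or p.false_drift_gain <= 0:
            return
        if self.t_hand_free > onset:  # hand busy travelling: no drift
            return
        target = self.centres[item]
        anchor = self.hand_pos.copy()
        vec = target - anchor
        dist = float(np.hypot(*vec))
        if dist < 1e-6:
            return
        drift_px = p.false_drift_gain * min(dist, 150.0)
        latency = 30.0  # motor-capture latency after the fixation lands
        budget_ms = offset - onset - latency
        if budget_ms <= 0:
            return
        # out and back within the fixation's budget, speed-limited
        drift_px = min(drift_px, budget_ms * p.hand_speed_px_s / 2000.0)
        if drift_px < 4.0:
            return
        u = vec / dist
        out = anchor + u * drift_px
        perp = np.array([-u[1], u[0]])
        back = anchor + perp * self.rng.uniform(2.0, 4.0) \
            * (1.0 if self.rng.random() < 0.5 else -1.0)
        if self._crosses_existing(anchor, out) or self._crosses_existing(out, back):
            return
        t0 = onset + latency
        d_out = drift_px / p.hand_speed_px_s * 1000.0
        d_back = float(np.hypot(*(back - out))) / p.hand_speed_px_s * 1000.0
        self.hand_legs.append((t0, t0 + d_out, anchor, out))
        self.hand_legs.append((t0 + d_out, t0 + d_out + d_back, out, back))
        if self.truth.first_move_ms is None:
            self.truth.first_move_ms = t0
        self.hand_pos = back
        self.t_hand_free = t0 + d_out + d_back

    def run(self) -> None:
        p = self.params
        # exploration: scan a few items before the hand moves
        for _ in range(p.exploration_fixations):
            j = self._unreached_other(-1)
            if j is None:
                break
            self.fixate(self.centres[j], j)
            if self.t_gaze > self.limit_ms:
                return

        while self.next_target < len(self.centres):
            k = self.next_target
            if self.t_gaze > self.limit_ms:
                return
            in_memory = p.memory_span > 0 and k in self.seen[-p.memory_span:]
            if in_memory:
                self._remembered_reach(k)
            else:
                if not self._search_and_reach(k):
                    return
            self.reached.add(k)
            if k in self.seen:
                self.seen.remove(k)
            self.next_target += 1

    def _remembered_reach(self, k: int) -> None:
        """Reach k directly; gaze inspects other items meanwhile."""
        arrive = self.hand_move(max(self.t_gaze, self.t_hand_free),
                                self.centres[k])
        # keep gaze busy on other items until the hand arrives
        while self.t_gaze < arrive:
            j = self._unreached_other(k)
            if j is None:
                self._scene_hop()
            else:
                self.fixate(self.centres[j], j)  # hand busy: no drift
        self.truth.remembered.append(k)
        self.truth.reached.append((k, arrive))

    def _scene_hop(self) -> None:
        """Fixate a nearby non-item scene spot.

        The hop is long enough for the connecting saccade to stay above
        the detection thresholds (keeps scheduled == detected counts).
        """
        ang = self.rng.uniform(0.0, 2.0 * math.pi)
        hop = self.rng.uniform(30.0, 60.0)
        step = hop * np.array([math.cos(ang), math.sin(ang)])
        dest = self.gaze_pos + step
        if np.any(dest < 5.0) or np.any(dest > 595.0):
            dest = self.gaze_pos - step  # hop inward at the border
        self.fixate(dest, None)

    def _search_and_reach(self, k: int) -> bool:
        """Search fixations until k is found, then reach it. False on timeout."""
        p = self.params
        while True:
            if self.t_gaze > self.limit_ms:
                return False
            others_left = any(j not in self.reached and j != k
                              for j in range(len(self.centres)))
            if self.rng.random() < p.search_accuracy or not others_left:
                break
            j = self._unreached_other(k)
            if j is None:  # only the current item is left to inspect
                self._scene_hop()
                continue
            onset, offset = self.fixate(self.centres[j], j)
            self._maybe_drift(j, onset, offset)
        # found: linger on k while the hand departs, so the fixation on k
        # ends strictly inside the departure -> arrival window (the
        # "saw the target again right before selecting it" case)
        gaze_dist = float(np.hypot(*(self.centres[k] - self.gaze_pos)))
        onset_est = self.t_gaze + (_saccade_duration(gaze_dist, p)
                                   if gaze_dist > 1e-6 else 0.0)
        hand_dist = float(np.hypot(*(self.centres[k] - self.hand_pos)))
        move_ms = hand_dist / p.hand_speed_px_s * 1000.0
        depart_floor = max(onset_est + 50.0, self.t_hand_free)
        dur = _fix_duration(p, self.rng)
        if move_ms > 20.0:
            lo = depart_floor - onset_est + 0.3 * move_ms
            hi = depart_floor - onset_est + 0.8 * move_ms
            dur = float(np.clip(dur, lo, max(lo, hi)))
        onset, offset = self.fixate(self.centres[k], k, duration=dur)
        depart = max(onset + 50.0, offset - 0.8 * move_ms, self.t_hand_free)
        arrive = self.hand_move(depart, self.centres[k])
        self.truth.reached.append((k, arrive))
        return True


def _ease(tau: np.ndarray) -> np.ndarray:
    """Symmetric (triangular-velocity) position profile on [0, 1]."""
    return np.where(tau < 0.5, 2.0 * tau**2, 1.0 - 2.0 * (1.0 - tau) ** 2)


def _render_gaze(builder: _TrialBuilder, rng: np.random.Generator,
                 ) -> GazeRecording:
    p = builder.params
    end = math.ceil(builder.t_gaze)
    t = np.arange(0.0, end + 1.0)
    x = np.full(len(t), _SCREEN_CENTRE[0])
    y = np.full(len(t), _SCREEN_CENTRE[1])
    for kind, t0, t1, p0, p1 in builder.gaze_segments:
        i0, i1 = int(math.ceil(t0)), min(int(math.floor(t1)), end)
        if i1 < i0:
            continue
        if kind == "fix":
            x[i0:i1 + 1] = p0[0]
            y[i0:i1 + 1] = p0[1]
        else:
            tau = (t[i0:i1 + 1] - t0) / max(t1 - t0, 1e-9)
            s = _ease(np.clip(tau, 0.0, 1.0))
            x[i0:i1 + 1] = p0[0] + s * (p1[0] - p0[0])
            y[i0:i1 + 1] = p0[1] + s * (p1[1] - p0[1])
    noise_px = p.gaze_noise_deg / p.deg_per_px
    if noise_px > 0:
        x = x + rng.normal(0.0, noise_px, len(x))
        y = y + rng.normal(0.0, noise_px, len(y))
    return GazeRecording(t=t, x=x, y=y, valid=np.ones(len(t), bool))


def _render_mouse(builder: _TrialBuilder) -> MouseTrajectory:
    """Mouse log: press sample at t=0, then samples only while moving."""
    t_end = max(builder.t_gaze, builder.t_hand_free)
    rows = [(0.0, _SCREEN_CENTRE[0], _SCREEN_CENTRE[1])]
    for t0, t1, a, b in sorted(builder.hand_legs, key=lambda lg: lg[0]):
        tt = np.arange(math.ceil(t0), math.floor(t1) + 1.0)
        if len(tt) == 0:
            tt = np.array([t1])
        tau = np.clip((tt - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
        for ti, u in zip(tt, tau):
            rows.append((float(ti), float(a[0] + u * (b[0] - a[0])),
                         float(a[1] + u * (b[1] - a[1]))))
        rows.append((float(t1), float(b[0]), float(b[1])))
    rows.append((float(t_end) + 1.0, rows[-1][1], rows[-1][2]))
    rows.sort(key=lambda r: r[0])
    # deduplicate identical timestamps (keep the later-scheduled position)
    dedup: dict[float, tuple] = {}
    for r in rows:
        dedup[r[0]] = r
    rows = sorted(dedup.values())
    t = np.array([r[0] for r in rows])
    return MouseTrajectory(t=t,
                           x=np.array([r[1] for r in rows]),
                           y=np.array([r[2] for r in rows]),
                           button=np.ones(len(rows), bool))


def simulate_trial(layout: StimulusLayout, params: AgentParameters,
                   seed: int) -> SimulatedTrial:
    """Simulate one trial on a labelled layout; deterministic under seed."""
    if not layout.labels:
        raise ValueError("simulate_trial needs a labelled layout")
    rng = np.random.default_rng(seed)
    builder = _TrialBuilder(layout, params, rng)
    builder.run()
    gaze = _render_gaze(builder, rng)
    mouse = _render_mouse(builder)
    return SimulatedTrial(layout=layout, gaze=gaze, mouse=mouse,
                          truth=builder.truth,
                          trial_type=layout.trial_type or "A", block=1)


def simulate_session(params: AgentParameters, layouts: list[StimulusLayout],
                     seed: int, *, participant: str = "sim",
                     trials_per_block: int = 20) -> SimulatedSession:
    """Simulate a session of strictly alternating A/B trials over ``layouts``.

    A full session uses 100 layouts (5 blocks of 20); reduced runs with an
    even number of layouts are supported.  Layout i is presented as type A
    when i is even and type B when odd, mirroring the strict alternation.
    """
    if len(layouts) % 2 != 0:
        raise ValueError("need an even number of layouts to alternate A/B")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(layouts))
    trials = []
    for i, (lay, child) in enumerate(zip(layouts, children)):
        ttype = "A" if i % 2 == 0 else "B"
        labelled = assign_labels(lay, ttype)
        tr = simulate_trial(labelled, params,
                            int(child.generate_state(1)[0] % 2**31))
        tr.block = i // trials_per_block + 1
        trials.append(tr)
    return SimulatedSession(participant=participant, params=params,
                            trials=trials)


def make_fixture_suite(out_dir, seed: int, *, n_participants: int = 3,
                       n_trials: int = 10) -> Path:
    """Write a small deterministic corpus exercising every reader.

    Layout JSONs, gaze/mouse CSVs and a manifest per participant, plus a
    deliberately corrupted gaze file (non-monotone timestamps) under
    ``corrupt/`` to exercise reader error paths.  Regenerating with the
    same seed reproduces the same tree.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = GridSpec()
    layouts, _ = generate_layout_set(grid, n_trials, seed)
    root = np.random.SeedSequence(seed + 1)
    for pi, pseed in enumerate(root.spawn(n_participants)):
        pdir = out / f"p{pi:02d}"
        pdir.mkdir(exist_ok=True)
        sess = simulate_session(AgentParameters(), layouts,
                                int(pseed.generate_state(1)[0] % 2**31),
                                participant=f"p{pi:02d}",
                                trials_per_block=max(2, n_trials // 5))
        entries = []
        for ti, tr in enumerate(sess.trials):
            lay_f, gaze_f, mouse_f = (f"trial{ti:03d}_layout.json",
                                      f"trial{ti:03d}_gaze.csv",
                                      f"trial{ti:03d}_mouse.csv")
            tr.layout.write_json(pdir / lay_f)
            write_gaze(tr.gaze, pdir / gaze_f)
            write_mouse(tr.mouse, pdir / mouse_f)
            entries.append({"layout": lay_f, "trial_type": tr.trial_type,
                            "block": tr.block, "gaze": gaze_f,
                            "mouse": mouse_f})
        with open(pdir / "manifest.json", "w") as fh:
            json.dump({"participant": sess.participant, "trials": entries}, fh,
                      indent=1)
    bad = out / "corrupt"
    bad.mkdir(exist_ok=True)
    (bad / "gaze_nonmonotone.csv").write_text(
        "t,x,y,valid\n0,100,100,1\n2,101,100,1\n1,102,100,1\n")
    (bad / "mouse_missing_button.csv").write_text("t,x,y\n0,1,2\n1,2,3\n")
    return out


def tree_hash(root) -> str:
    """SHA-256 over the sorted relative paths and contents of a file tree."""
    h = hashlib.sha256()
    root = Path(root)
    for f in sorted(root.rglob("*")):
        if f.is_file():
            h.update(str(f.relative_to(root)).encode())
            h.update(f.read_bytes())
    return h.hexdigest()
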