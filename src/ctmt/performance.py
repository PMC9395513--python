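"""Per-trial scoring from the mouse trajectory.

A target counts as reached when the cursor path comes within 10 px of its
centre.  A trial is *completed* when the first 12 items of the trail are
entered in order (as a subsequence of all entries — wrong items touched
and corrected in between are tolerated) within the 25 s limit; RT is the
time from the button press to the 12th in-order entry.  A trial is
*correct* when it is completed, no out-of-order item is entered before
completion, and the drawn trajectory never touches itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

from .io import MouseTrajectory
from .stimuli import StimulusLayout

__all__ = [
    "PerformanceConfig",
    "Reach",
    "TrialResult",
    "detect_reaches",
    "evaluate_trial",
    "trajectory_self_crossing",
    "aggregate_performance",
    "split_terciles",
]


@dataclass(frozen=True)
class PerformanceConfig:
    reach_radius_px: float = 10.0
    completion_items: int = 12
    trial_limit_s: float = 25.0
    #: if True, "successfully completed" additionally demands strict
    #: correctness (no out-of-order entries, no self-crossing)
    require_correct: bool = False

    def __post_init__(self) -> None:
        if min(self.reach_radius_px, self.completion_items, self.trial_limit_s) <= 0:
            raise ValueError("all performance parameters must be positive")


@dataclass(frozen=True)
class Reach:
    """First entry of the cursor into an item's reach circle."""

    item: int  # 0-based index in path order
    t_entry: float  # ms
    t_exit: float  # ms, last time inside before leaving (or trajectory end)


@dataclass
class TrialResult:
    entries: list[Reach]
    completed: bool
    correct: bool
    rt_s: float | None  # present iff completed
    n_concatenated: int
    self_crossing: bool
    trial_type: str | None = None
    block: int | None = None
    extras: dict = field(default_factory=dict)


def detect_reaches(mouse: MouseTrajectory, layout: StimulusLayout,
                   cfg: PerformanceConfig | None = None) -> list[Reach]:
    """Chronological item entries of the cursor path.

    The test is segment-based: an entry fires when the minimum distance
    from any inter-sample path segment to the item centre falls within the
    reach radius, so fast cursor jumps across a circle are not missed.
    Re-entries after leaving the circle are new events.
    """
    cfg = cfg or PerformanceConfig()
    if len(mouse) < 2:
        return []
    t = mouse.t
    xs, ys = mouse.x, mouse.y
    centres = np.asarray(layout.positions, float)
    r = cfg.reach_radius_px
    reaches: list[Reach] = []

    # exact in-circle intervals of each linear path segment (quadratic roots),
    # so a leave-and-re-enter within one sampling gap still counts twice
    ax, ay = xs[:-1], ys[:-1]
    dx, dy = np.diff(xs), np.diff(ys)
    dt = np.diff(t)
    seg_ok = mouse.button[:-1] & mouse.button[1:]
    A = dx * dx + dy * dy
    for k, (cx, cy) in enumerate(centres):
        fx, fy = ax - cx, ay - cy
        B = 2.0 * (fx * dx + fy * dy)
        C = fx * fx + fy * fy - r * r
        disc = B * B - 4.0 * A * C
        with np.errstate(invalid="ignore", divide="ignore"):
            sq = np.sqrt(np.maximum(disc, 0.0))
            u1 = np.where(A > 0, (-B - sq) / (2.0 * A), 0.0)
            u2 = np.where(A > 0, (-B + sq) / (2.0 * A), 1.0)
        inside = np.where(A > 0, disc >= 0, C <= 0) & seg_ok
        u1c = np.clip(u1, 0.0, 1.0)
        u2c = np.clip(u2, 0.0, 1.0)
        hit = inside & (u2 >= 0.0) & (u1 <= 1.0) & (u2c > u1c - 1e-12)
        idx = np.flatnonzero(hit)
        if idx.size == 0:
            continue
        t_in = t[idx] + u1c[idx] * dt[idx]
        t_out = t[idx] + u2c[idx] * dt[idx]
        # merge intervals that abut through a shared sample point
        cur_in, cur_out = t_in[0], t_out[0]
        for ti, to in zip(t_in[1:], t_out[1:]):
            if ti <= cur_out + 1e-9:
                cur_out = max(cur_out, to)
            else:
                reaches.append(Reach(item=k, t_entry=float(cur_in),
                                     t_exit=float(cur_out)))
                cur_in, cur_out = ti, to
        reaches.append(Reach(item=k, t_entry=float(cur_in),
                             t_exit=float(cur_out)))
    reaches.sort(key=lambda r: r.t_entry)
    return reaches


def trajectory_self_crossing(mouse: MouseTrajectory) -> bool:
    """Does the drawn cursor path touch or cross itself?

    Uses the simplicity test of the path polyline (self-tangency counts);
    consecutive duplicate points are collapsed first.
    """
    pts = np.stack([mouse.x, mouse.y], axis=1)
    keep = np.r_[True, np.any(np.diff(pts, axis=0) != 0, axis=1)]
    pts = pts[keep]
    if len(pts) < 3:
        return False
    return not LineString(pts).is_simple


def evaluate_trial(entries: list[Reach], layout: StimulusLayout,
                   cfg: PerformanceConfig | None = None,
                   *,
                   self_crossing: bool = False,
                   t_start: float = 0.0) -> TrialResult:
    """Score a trial from its chronological entry sequence.

    ``t_start`` is the button-press timestamp (trial onset); entries later
    than the trial limit are ignored for completion.
    """
    cfg = cfg or PerformanceConfig()
    limit_ms = cfg.trial_limit_s * 1000.0
    need = list(range(min(cfg.completion_items, layout.n_items)))

    next_pos = 0  # position in `need` of the next required item
    rt_ms: float | None = None
    out_of_order = False
    for r in entries:
        if r.t_entry - t_start > limit_ms:
            break
        if next_pos < len(need) and r.item == need[next_pos]:
            next_pos += 1
            if next_pos == len(need):
                rt_ms = r.t_entry - t_start
                break
        elif r.item != (need[next_pos - 1] if next_pos > 0 else None):
            # an entry into anything but the current or the expected item
            out_of_order = True
    completed = rt_ms is not None
    correct = completed and not out_of_order and not self_crossing
    return TrialResult(
        entries=list(entries),
        completed=completed if not cfg.require_correct else (completed and correct),
        correct=correct,
        rt_s=(rt_ms / 1000.0) if completed else None,
        n_concatenated=next_pos,
        self_crossing=self_crossing,
        trial_type=layout.trial_type,
    )


def aggregate_performance(results: list[TrialResult]) -> dict:
    """Percentage of completion, RT summary and B/A ratios per condition.

    PC is the percentage of trials completed up to the criterion item; RT
    is summarised per condition by the median over completed trials.
    The Completion Ratio is PC-B/PC-A and the RT Ratio is RT-B/RT-A;
    a zero or undefined denominator flags the ratio as undefined (None).
    """
    out: dict = {}
    for cond in ("A", "B"):
        sub = [r for r in results if r.trial_type == cond]
        if not sub:
            continue
        pc = 100.0 * sum(r.completed for r in sub) / len(sub)
        rts = [r.rt_s for r in sub if r.rt_s is not None]
        out[cond] = {
            "n_trials": len(sub),
            "pc": pc,
            "rt_median_s": float(np.median(rts)) if rts else None,
        }
    if "A" in out and "B" in out:
        pa, pb = out["A"]["pc"], out["B"]["pc"]
        out["completion_ratio"] = (pb / pa) if pa > 0 else None
        ra, rb = out["A"]["rt_median_s"], out["B"]["rt_median_s"]
        out["rt_ratio"] = (rb / ra) if (ra and rb) else None
    return out


def split_terciles(trials: list) -> tuple[list, list]:
    """Chronological first and last thirds; the middle third is discarded.

    When the count is not divisible by three the remainder goes to the
    earlier terciles (100 trials -> 34 first / 33 last).
    """
    n = len(trials)
    if n < 3:
        raise ValueError("need at least 3 trials to form terciles")
    base, rem = divmod(n, 3)
    n_first = base + (1 if rem >= 1 else 0)
    n_last = base
    return list(trials[:n_first]), list(trials[n - n_last:])
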