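"""Inhibitory-control metric from fixation-aligned hand trajectories.

For every fixation assigned to an item, the hand path over the fixation
interval is translated so the hand's position at fixation onset is the
origin, projected on the unit vector from that origin position toward the
fixated item, and normalised by the origin-to-item distance, so the item
sits at projected coordinate 1 (and at (1, 0) in the 2-D form).
Fixations on the next item in the sequence are Correct Detections; all
others are False Detections — hand drift toward a falsely detected item
betrays an inhibition failure.  The per-participant metric is the
trapezoidal area, 50-300 ms after fixation onset, under the difference
between the mean Correct and mean False projection curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MouseTrajectory
from .memory import AssignedFixation
from .performance import TrialResult
from .stimuli import StimulusLayout

__all__ = [
    "InhibitionConfig",
    "DetectionEvent",
    "segment_and_project",
    "classify_detection",
    "displacement_curves",
    "spatial_histogram",
]


@dataclass(frozen=True)
class InhibitionConfig:
    auc_window_ms: tuple[float, float] = (50.0, 300.0)
    min_events_per_kind: int = 1
    #: "ragged" averages over all events still ongoing at each lag;
    #: "truncate" keeps only events lasting the whole AUC window
    pooling: str = "ragged"

    def __post_init__(self) -> None:
        lo, hi = self.auc_window_ms
        if not 0 <= lo < hi:
            raise ValueError("auc_window_ms must be an increasing interval")
        if self.pooling not in ("ragged", "truncate"):
            raise ValueError("pooling must be 'ragged' or 'truncate'")
        if self.min_events_per_kind < 1:
            raise ValueError("min_events_per_kind must be >= 1")


@dataclass
class DetectionEvent:
    """One fixation-aligned, normalised hand-path segment."""

    kind: str  # "correct" | "false"
    lags_ms: np.ndarray  # 1 ms grid from fixation onset
    projection: np.ndarray  # displacement toward the item; item at 1
    path_2d: np.ndarray  # (n, 2) normalised path, item at (1, 0)
    item: int
    trial_type: str | None = None


def classify_detection(item: int, next_expected: int) -> str:
    """"correct" iff the fixated item is the next unreached item in order."""
    return "correct" if item == next_expected else "false"


def _next_expected_at(trial: TrialResult, t: float) -> int:
    """Next unreached required item (path order) at time t."""
    nxt = 0
    for r in trial.entries:
        if r.t_entry >= t:
            break
        if r.item == nxt:
            nxt += 1
    return nxt


def segment_and_project(trial: TrialResult,
                        assigned: list[AssignedFixation],
                        mouse: MouseTrajectory,
                        layout: StimulusLayout) -> list[DetectionEvent]:
    """Build detection events for every item-assigned fixation of a trial.

    Unassigned fixations yield no event; a fixation whose onset hand
    position coincides with the item centre (zero normalising distance)
    is dropped.  The cursor is interpolated by zero-order hold at 1 ms.
    """
    centres = np.asarray(layout.positions, float)
    events: list[DetectionEvent] = []
    for a in assigned:
        if a.item is None:
            continue
        f = a.fixation
        lags = np.arange(0.0, f.offset - f.onset + 0.5)
        if len(lags) < 2:
            continue
        pos = mouse.position_at(f.onset + lags)
        origin = pos[0]
        target = centres[a.item] - origin
        dist = float(np.hypot(*target))
        if dist == 0.0:
            continue  # degenerate: hand already on the item at onset
        u = target / dist
        u_perp = np.array([-u[1], u[0]])
        rel = pos - origin
        proj = rel @ u / dist
        perp = rel @ u_perp / dist
        kind = classify_detection(a.item, _next_expected_at(trial, f.onset))
        events.append(DetectionEvent(
            kind=kind, lags_ms=lags, projection=proj,
            path_2d=np.stack([proj, perp], axis=1),
            item=a.item, trial_type=trial.trial_type,
        ))
    return events


def displacement_curves(events: list[DetectionEvent],
                        cfg: InhibitionConfig | None = None) -> dict:
    """Mean Correct / False projection curves, their difference, and the AUC.

    At each 1 ms lag the mean runs over the events still ongoing at that
    lag (ragged averaging), unless ``pooling='truncate'`` restricts to
    events covering the whole AUC window.  The AUC is the trapezoidal
    integral of (correct - false) over the window, in dimensionless
    displacement x seconds; it is computed participant-by-participant by
    the caller feeding per-participant event lists.
    """
    cfg = cfg or InhibitionConfig()
    lo, hi = cfg.auc_window_ms
    out: dict = {"auc": None, "n_correct": 0, "n_false": 0}
    curves: dict[str, np.ndarray | None] = {}
    for kind in ("correct", "false"):
        evs = [e for e in events if e.kind == kind]
        if cfg.pooling == "truncate":
            evs = [e for e in evs if e.lags_ms[-1] >= hi]
        out[f"n_{kind}"] = len(evs)
        if len(evs) < cfg.min_events_per_kind:
            curves[kind] = None
            continue
        max_lag = int(max(e.lags_ms[-1] for e in evs))
        sums = np.zeros(max_lag + 1)
        counts = np.zeros(max_lag + 1)
        for e in evs:
            n = len(e.projection)
            sums[:n] += e.projection
            counts[:n] += 1
        with np.errstate(invalid="ignore"):
            curves[kind] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        curves[f"n_{kind}_per_lag"] = counts
    out["correct_curve"] = curves.get("correct")
    out["false_curve"] = curves.get("false")
    if curves.get("correct") is None or curves.get("false") is None:
        return out  # a kind with too few events: flagged by auc=None
    m = min(len(curves["correct"]), len(curves["false"]))
    diff = curves["correct"][:m] - curves["false"][:m]
    out["difference_curve"] = diff
    lags = np.arange(m, dtype=float)
    sel = (lags >= lo) & (lags <= hi) & np.isfinite(diff)
    if sel.sum() >= 2:
        out["auc"] = float(np.trapezoid(diff[sel], lags[sel] / 1000.0))
    return out


def spatial_histogram(events: list[DetectionEvent],
                      bins: int = 50,
                      extent: tuple[float, float, float, float] = (-1.5, 2.5, -2.0, 2.0),
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of the normalised hand paths, item at (1, 0).

    Returns (H, xedges, yedges); bin counts sum to the number of path
    samples falling inside the extent.
    """
    if not events:
        raise ValueError("spatial_histogram needs at least one event")
    pts = np.concatenate([e.path_2d for e in events], axis=0)
    x0, x1, y0, y1 = extent
    H, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins,
                               range=[[x0, x1], [y0, y1]])
    return H, xe, ye
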