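"""Three-phase fixation taxonomy: exploration, monitoring, planning.

Fixations occurring before the first hand movement of a trial are
*exploration* fixations — the initial scan of the scene.  After the hand
starts moving, a fixation is *monitoring* if gaze comes closer than 25 px
to the cursor at any moment of the fixation interval, and *planning* if
it stays at 25 px or farther throughout.  The gaze-cursor distance is
evaluated at 1 ms resolution using the instantaneous gaze samples against
the zero-order-hold cursor, since "any time during the fixation" is a
statement about the continuous interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import Fixation
from .io import GazeRecording, MouseTrajectory

__all__ = [
    "PhaseConfig",
    "PhaseLabeledFixation",
    "first_hand_movement",
    "classify_fixation",
    "classify_fixations",
    "phase_summary",
]

PHASES = ("exploration", "monitoring", "planning")


@dataclass(frozen=True)
class PhaseConfig:
    cursor_radius_px: float = 25.0
    #: displacement from the press-time position that counts as "the hand
    #: moved"; guards against sensor jitter (0 gives the literal reading)
    first_move_epsilon_px: float = 2.0
    #: a fixation straddling the first movement is exploration if its
    #: *onset* precedes it; "offset" assigns it by its end instead
    straddle_rule: str = "onset"

    def __post_init__(self) -> None:
        if self.cursor_radius_px <= 0:
            raise ValueError("cursor_radius_px must be positive")
        if self.straddle_rule not in ("onset", "offset"):
            raise ValueError("straddle_rule must be 'onset' or 'offset'")


@dataclass(frozen=True)
class PhaseLabeledFixation:
    fixation: Fixation
    phase: str
    min_cursor_distance_px: float


def first_hand_movement(mouse: MouseTrajectory,
                        cfg: PhaseConfig | None = None) -> float | None:
    """Earliest time the cursor leaves its press-time position.

    Returns the first timestamp at which the displacement from the
    position at button press exceeds ``first_move_epsilon_px``; ``None``
    if the cursor never moves that far (all fixations are exploratory).
    """
    cfg = cfg or PhaseConfig()
    held = np.flatnonzero(mouse.button)
    if held.size == 0:
        return None
    i0 = held[0]
    x0, y0 = mouse.x[i0], mouse.y[i0]
    disp = np.hypot(mouse.x[i0:] - x0, mouse.y[i0:] - y0)
    moved = np.flatnonzero(disp > cfg.first_move_epsilon_px)
    if moved.size == 0:
        return None
    return float(mouse.t[i0 + moved[0]])


def _min_gaze_cursor_distance(fix: Fixation, gaze: GazeRecording,
                              mouse: MouseTrajectory) -> float:
    """Min distance between gaze samples and the ZOH cursor over the fixation."""
    sel = (gaze.t >= fix.onset) & (gaze.t <= fix.offset) & gaze.valid
    if not np.any(sel):
        return float("inf")
    cur = mouse.position_at(gaze.t[sel])
    d = np.hypot(gaze.x[sel] - cur[..., 0], gaze.y[sel] - cur[..., 1])
    return float(d.min())


def classify_fixation(fix: Fixation, gaze: GazeRecording, mouse: MouseTrajectory,
                      t_move: float | None,
                      cfg: PhaseConfig | None = None) -> PhaseLabeledFixation:
    """Assign one fixation to exploration, monitoring or planning.

    A fixation at exactly the cursor radius is planning (strict "closer
    than").  ``t_move`` is the first-hand-movement time (None if the hand
    never moved).
    """
    cfg = cfg or PhaseConfig()
    dmin = _min_gaze_cursor_distance(fix, gaze, mouse)
    anchor = fix.onset if cfg.straddle_rule == "onset" else fix.offset
    if t_move is None or anchor < t_move:
        phase = "exploration"
    elif dmin < cfg.cursor_radius_px:
        phase = "monitoring"
    else:
        phase = "planning"
    return PhaseLabeledFixation(fixation=fix, phase=phase,
                                min_cursor_distance_px=dmin)


def classify_fixations(fixations: list[Fixation], gaze: GazeRecording,
                       mouse: MouseTrajectory,
                       cfg: PhaseConfig | None = None) -> list[PhaseLabeledFixation]:
    """Label every fixation of a trial (computes ``t_move`` once)."""
    cfg = cfg or PhaseConfig()
    t_move = first_hand_movement(mouse, cfg)
    return [classify_fixation(f, gaze, mouse, t_move, cfg) for f in fixations]


def phase_summary(trials: dict[str, list[list[PhaseLabeledFixation]]]) -> dict:
    """Per-phase mean fixation count per trial and median duration, with B/A ratios.

    ``trials`` maps condition ("A"/"B") to a list of per-trial labelled
    fixation lists.  A phase with zero fixations reports count 0 and no
    duration; ratios are None when the A-side value is missing or zero.
    """
    out: dict = {}
    for cond, trial_lists in trials.items():
        stats: dict = {}
        for phase in PHASES:
            counts = [sum(lf.phase == phase for lf in tr) for tr in trial_lists]
            durs = [lf.fixation.duration for tr in trial_lists
                    for lf in tr if lf.phase == phase]
            stats[phase] = {
                "mean_count": float(np.mean(counts)) if counts else 0.0,
                "median_duration_ms": float(np.median(durs)) if durs else None,
            }
        out[cond] = stats
    if "A" in out and "B" in out:
        ratios: dict = {}
        for phase in PHASES:
            a, b = out["A"][phase], out["B"][phase]
            ratios[phase] = {
                "count_ratio": (b["mean_count"] / a["mean_count"])
                if a["mean_count"] else None,
                "duration_ratio": (b["median_duration_ms"] / a["median_duration_ms"])
                if (a["median_duration_ms"] and b["median_duration_ms"]) else None,
            }
        out["ratios"] = ratios
    return out
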