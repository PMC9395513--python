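"""Internal working-memory metric (Targets Remembered) and CDT capacity K.

A target is *remembered* when it was seen earlier in the trial and then
reached with the hand without a re-fixation immediately before the reach:
at least one fixation assigned to the target ends before the hand departs
the previous target, and no fixation assigned to it falls in the interval
between departing the previous target and reaching it.  Any number of
intervening fixations on *other* items is irrelevant.  Only correct
trials enter the metric.

The external visual working-memory capacity from a change detection task
is K = N_set * (2 * correct/all - 1) per set size (4 or 6), with
K_average their mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import Fixation
from .performance import Reach, TrialResult
from .stimuli import StimulusLayout

__all__ = [
    "MemoryConfig",
    "AssignedFixation",
    "assign_fixations_to_items",
    "targets_remembered",
    "tr_summary",
    "cdt_k",
]


@dataclass(frozen=True)
class MemoryConfig:
    #: max centroid-to-centre distance for a fixation to count as "on" an item
    assign_radius_px: float = 50.0
    block_min_correct: int = 3
    n_blocks: int = 5

    def __post_init__(self) -> None:
        if self.assign_radius_px <= 0 or self.block_min_correct < 1:
            raise ValueError("invalid memory configuration")


@dataclass(frozen=True)
class AssignedFixation:
    fixation: Fixation
    item: int | None  # 0-based path-order index, None if unassigned


def assign_fixations_to_items(fixations: list[Fixation], layout: StimulusLayout,
                              cfg: MemoryConfig | None = None,
                              ) -> list[AssignedFixation]:
    """Assign each fixation to its nearest item centre within the radius.

    Ties in distance break toward the earlier item in path order (the
    argmin convention); fixations farther than the radius from every
    centre stay unassigned.
    """
    cfg = cfg or MemoryConfig()
    centres = np.asarray(layout.positions, float)
    out = []
    for f in fixations:
        d = np.hypot(centres[:, 0] - f.cx, centres[:, 1] - f.cy)
        k = int(np.argmin(d))  # argmin returns the first (earlier) index on ties
        out.append(AssignedFixation(fixation=f,
                                    item=k if d[k] <= cfg.assign_radius_px else None))
    return out


def targets_remembered(trial: TrialResult,
                       assigned: list[AssignedFixation],
                       *, force: bool = False) -> int:
    """Count of remembered targets in one correct trial.

    Counted from the second concatenated target onward (the first target
    has no previous-target departure to anchor the window).  For target T
    reached at ``t_reach`` after departing the previous target at
    ``t_depart``: remembered iff some fixation assigned to T ends at or
    before ``t_depart`` and no fixation assigned to T ends inside
    ``(t_depart, t_reach)``.

    Raises unless the trial is correct (the metric only includes correct
    trials); ``force=True`` overrides for diagnostics.
    """
    if not trial.correct and not force:
        raise ValueError("targets_remembered is defined on correct trials only")

    # chronological first-reach per required item, in concatenation order
    seq: list[Reach] = []
    nxt = 0
    for r in trial.entries:
        if r.item == nxt:
            seq.append(r)
            nxt += 1
        if nxt >= trial.n_concatenated:
            break
    tr = 0
    for prev, cur in zip(seq[:-1], seq[1:]):
        t_depart = prev.t_exit  # last timestamp inside the previous circle
        t_reach = cur.t_entry
        fix_on_target = [a.fixation for a in assigned if a.item == cur.item]
        seen_before = any(f.offset <= t_depart for f in fix_on_target)
        refixated = any(t_depart < f.offset < t_reach for f in fix_on_target)
        if seen_before and not refixated:
            tr += 1
    return tr


def tr_summary(sessions: dict[str, list[tuple[TrialResult, int]]],
               cfg: MemoryConfig | None = None) -> dict:
    """Mean TR per condition, TR ratio, and the block-wise ratio variant.

    ``sessions`` maps condition to a list of ``(TrialResult, tr_count)``
    over that participant's *correct* trials (TrialResult.block set).
    Block-wise ratios use only blocks with at least ``block_min_correct``
    correct trials in each part; the summary reports both the retained
    ratios and the excluded blocks.
    """
    cfg = cfg or MemoryConfig()
    out: dict = {}
    for cond in ("A", "B"):
        trs = [tr for _, tr in sessions.get(cond, [])]
        out[cond] = {"n_correct": len(trs),
                     "mean_tr": float(np.mean(trs)) if trs else None}
    a, b = out["A"]["mean_tr"], out["B"]["mean_tr"]
    out["tr_ratio"] = (b / a) if (a and b is not None) else None
    out["excluded"] = out["A"]["mean_tr"] is None or out["B"]["mean_tr"] is None

    block_ratios: dict[int, float | None] = {}
    excluded_blocks: list[int] = []
    for blk in range(1, cfg.n_blocks + 1):
        per_cond = {}
        for cond in ("A", "B"):
            vals = [tr for res, tr in sessions.get(cond, []) if res.block == blk]
            per_cond[cond] = vals
        if any(len(per_cond[c]) < cfg.block_min_correct for c in ("A", "B")):
            excluded_blocks.append(blk)
            continue
        ma, mb = np.mean(per_cond["A"]), np.mean(per_cond["B"])
        block_ratios[blk] = float(mb / ma) if ma else None
    out["block_tr_ratios"] = block_ratios
    out["excluded_blocks"] = excluded_blocks
    return out


def cdt_k(table: list[dict]) -> dict:
    """Capacity estimates from a change-detection trial table.

    ``table`` rows carry ``set_size`` (4 or 6) and ``correct`` (bool).
    K = N_set * (2 * prop_correct - 1); K_average needs both set sizes.
    """
    out: dict = {"K4": None, "K6": None, "K_average": None}
    for n_set in (4, 6):
        rows = [r for r in table if r["set_size"] == n_set]
        if any(r["set_size"] not in (4, 6) for r in table):
            raise ValueError("set_size must be 4 or 6")
        if rows:
            prop = sum(bool(r["correct"]) for r in rows) / len(rows)
            out[f"K{n_set}"] = n_set * (2.0 * prop - 1.0)
    if out["K4"] is not None and out["K6"] is not None:
        out["K_average"] = (out["K4"] + out["K6"]) / 2.0
    return out
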