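"""End-to-end analysis of a trial or session.

Glue over the stage modules: event detection and filtering, reach
scoring, phase labelling, fixation-to-item assignment, the
targets-remembered count and the inhibition detection events — run in
the order a real recording would flow through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventThresholds, EventSequence, detect_events, filter_events
from .inhibition import DetectionEvent, InhibitionConfig, displacement_curves, \
    segment_and_project
from .io import GazeRecording, MouseTrajectory
from .memory import AssignedFixation, MemoryConfig, assign_fixations_to_items, \
    targets_remembered
from .performance import PerformanceConfig, TrialResult, detect_reaches, \
    evaluate_trial, trajectory_self_crossing
from .phases import PhaseConfig, PhaseLabeledFixation, classify_fixations
from .stimuli import StimulusLayout

__all__ = ["TrialAnalysis", "PipelineConfig", "analyze_trial", "analyze_session"]


@dataclass(frozen=True)
class PipelineConfig:
    thresholds: EventThresholds = field(default_factory=EventThresholds)
    performance: PerformanceConfig = field(default_factory=PerformanceConfig)
    phases: PhaseConfig = field(default_factory=PhaseConfig)
    memory: MemoryConfig = field(default_factory=MemoryConfig)
    inhibition: InhibitionConfig = field(default_factory=InhibitionConfig)


@dataclass
class TrialAnalysis:
    result: TrialResult
    events: EventSequence
    labeled_fixations: list[PhaseLabeledFixation]
    assigned: list[AssignedFixation]
    tr: int | None  # targets remembered; None unless the trial is correct
    detections: list[DetectionEvent]


def analyze_trial(gaze: GazeRecording, mouse: MouseTrajectory,
                  layout: StimulusLayout,
                  cfg: PipelineConfig | None = None,
                  *, trial_type: str | None = None,
                  block: int | None = None) -> TrialAnalysis:
    """Run the full per-trial pipeline on one recording triple."""
    cfg = cfg or PipelineConfig()
    events = filter_events(detect_events(gaze, cfg.thresholds))
    reaches = detect_reaches(mouse, layout, cfg.performance)
    crossing = trajectory_self_crossing(mouse)
    result = evaluate_trial(reaches, layout, cfg.performance,
                            self_crossing=crossing,
                            t_start=mouse.press_time() if len(mouse) else 0.0)
    result.trial_type = trial_type or layout.trial_type
    result.block = block
    labeled = classify_fixations(events.fixations, gaze, mouse, cfg.phases)
    assigned = assign_fixations_to_items(events.fixations, layout, cfg.memory)
    tr = targets_remembered(result, assigned) if result.correct else None
    detections = segment_and_project(result, assigned, mouse, layout)
    return TrialAnalysis(result=result, events=events, labeled_fixations=labeled,
                         assigned=assigned, tr=tr, detections=detections)


def analyze_session(trials, cfg: PipelineConfig | None = None) -> dict:
    """Analyse an iterable of simulated trials; aggregate per condition.

    Returns per-trial analyses plus condition-level inputs for the
    summary functions: TR pairs per condition, pooled detection events,
    and the per-condition inhibition AUC.
    """
    cfg = cfg or PipelineConfig()
    analyses = []
    tr_sessions: dict[str, list] = {"A": [], "B": []}
    detections: dict[str, list] = {"A": [], "B": []}
    for tr in trials:
        an = analyze_trial(tr.gaze, tr.mouse, tr.layout, cfg,
                           trial_type=tr.trial_type, block=tr.block)
        analyses.append(an)
        cond = an.result.trial_type
        if cond in tr_sessions:
            if an.tr is not None:
                tr_sessions[cond].append((an.result, an.tr))
            detections[cond].extend(an.detections)
    out: dict = {"analyses": analyses, "tr_sessions": tr_sessions,
                 "detections": detections}
    all_det = detections["A"] + detections["B"]
    out["inhibition"] = displacement_curves(all_det, cfg.inhibition)
    mean_trs = [t for pairs in tr_sessions.values() for _, t in pairs]
    out["mean_tr"] = float(np.mean(mean_trs)) if mean_trs else None
    return out
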