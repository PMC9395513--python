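"""Fixation-aligned hand projection curves and the inhibition AUC."""

import numpy as np
import pytest

from ctmt.events import Fixation
from ctmt.inhibition import (
    DetectionEvent,
    InhibitionConfig,
    classify_detection,
    displacement_curves,
    segment_and_project,
    spatial_histogram,
)
from ctmt.io import MouseTrajectory
from ctmt.memory import assign_fixations_to_items
from ctmt.performance import Reach, TrialResult
from ctmt.stimuli import StimulusLayout


def layout_at(positions):
    pos = np.asarray(positions, float)
    return StimulusLayout(positions=pos,
                          labels=[str(i + 1) for i in range(len(pos))])


def linear_mouse(p0, p1, t0, t1, n=200):
    t = np.linspace(t0, t1, n)
    u = (t - t0) / (t1 - t0)
    return MouseTrajectory(t=t, x=p0[0] + u * (p1[0] - p0[0]),
                           y=p0[1] + u * (p1[1] - p0[1]),
                           button=np.ones(n, bool))


def project_events(lay, mouse, fix, entries=()):
    trial = TrialResult(entries=list(entries), completed=True, correct=True,
                        rt_s=5.0, n_concatenated=0, self_crossing=False,
                        trial_type="A")
    assigned = assign_fixations_to_items([fix], lay)
    return segment_and_project(trial, assigned, mouse, lay)


class TestSegmentAndProject:
    def test_linear_approach_rises_to_one(self):
        lay = layout_at([(300, 100)])
        m = linear_mouse((100, 100), (300, 100), 0, 400)
        ev, = project_events(lay, m, Fixation(0, 400, 300, 100))
        assert ev.projection[0] == pytest.approx(0.0, abs=1e-6)
        assert ev.projection[-1] == pytest.approx(1.0, abs=0.02)
        assert np.all(np.diff(ev.projection) >= -1e-9)

    def test_stationary_hand_flat_zero(self):
        lay = layout_at([(300, 100)])
        m = MouseTrajectory(t=[0.0], x=[100.0], y=[100.0], button=[True])
        ev, = project_events(lay, m, Fixation(0, 300, 300, 100))
        assert np.allclose(ev.projection, 0.0)

    def test_perpendicular_motion_projects_to_zero(self):
        lay = layout_at([(300, 100)])
        m = linear_mouse((100, 100), (100, 300), 0, 400)  # straight down
        ev, = project_events(lay, m, Fixation(0, 400, 300, 100))
        assert np.allclose(ev.projection, 0.0, atol=1e-9)
        # all motion shows up on the perpendicular axis of the 2-D path
        assert abs(ev.path_2d[-1, 1]) == pytest.approx(1.0, abs=0.02)

    def test_onset_on_item_dropped(self):
        lay = layout_at([(100, 100)])
        m = MouseTrajectory(t=[0.0], x=[100.0], y=[100.0], button=[True])
        assert project_events(lay, m, Fixation(0, 300, 100, 100)) == []

    def test_normalisation_affine_invariance(self, rng):
        """Arrival projects to 1 under any rotation + translation."""
        for _ in range(15):
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
            shift = rng.uniform(-500, 500, 2)
            start = R @ np.array([100.0, 100.0]) + shift
            item = R @ np.array([340.0, 180.0]) + shift
            lay = layout_at([item])
            m = linear_mouse(start, item, 0, 350)
            ev, = project_events(lay, m, Fixation(0, 350, *item))
            assert ev.projection[-1] == pytest.approx(1.0, abs=0.02)


class TestClassifyDetection:
    def test_kinds(self):
        assert classify_detection(3, 3) == "correct"
        assert classify_detection(2, 3) == "false"  # already-passed item
        assert classify_detection(5, 3) == "false"  # two steps ahead

    def test_next_expected_state_from_entries(self):
        lay = layout_at([(100, 100), (300, 100), (500, 100)])
        entries = [Reach(0, 1000.0, 1200.0)]
        m = linear_mouse((100, 100), (300, 100), 1200, 1500)
        trial = TrialResult(entries=entries, completed=True, correct=True,
                            rt_s=5.0, n_concatenated=1, self_crossing=False,
                            trial_type="A")
        fix_next = Fixation(1250, 1450, 300, 100)  # on item 1 == next
        fix_ahead = Fixation(1250, 1450, 500, 100)  # on item 2
        assigned = assign_fixations_to_items([fix_next, fix_ahead], lay)
        evs = segment_and_project(trial, assigned, m, lay)
        assert [e.kind for e in evs] == ["correct", "false"]


def const_event(kind, value, n=400):
    lags = np.arange(float(n))
    return DetectionEvent(kind=kind, lags_ms=lags,
                          projection=np.full(n, float(value)),
                          path_2d=np.zeros((n, 2)), item=0)


class TestDisplacementCurves:
    def test_identical_curves_zero_auc(self):
        evs = [const_event("correct", 0.7), const_event("false", 0.7)]
        out = displacement_curves(evs)
        assert out["auc"] == pytest.approx(0.0, abs=1e-12)

    def test_unit_rectangle_auc(self):
        """correct=1, false=0 over the window: area = 250 ms * 1 = 0.250 s."""
        evs = [const_event("correct", 1.0), const_event("false", 0.0)]
        out = displacement_curves(evs)
        assert out["auc"] == pytest.approx(0.250, abs=1e-9)

    def test_missing_kind_flagged(self):
        out = displacement_curves([const_event("correct", 1.0)])
        assert out["auc"] is None
        assert out["n_false"] == 0

    def test_ragged_averaging_uses_ongoing_events(self):
        evs = [const_event("correct", 1.0, n=100),
               const_event("correct", 0.0, n=400),
               const_event("false", 0.0, n=400)]
        out = displacement_curves(evs)
        c = out["correct_curve"]
        assert c[50] == pytest.approx(0.5)  # both events ongoing
        assert c[200] == pytest.approx(0.0)  # only the long event remains

    def test_truncate_mode_drops_short_events(self):
        evs = [const_event("correct", 1.0, n=100),
               const_event("correct", 0.0, n=400),
               const_event("false", 0.0, n=400)]
        out = displacement_curves(evs, InhibitionConfig(pooling="truncate"))
        assert out["n_correct"] == 1
        assert np.allclose(out["correct_curve"], 0.0)


class TestSpatialHistogram:
    def test_straight_path_mass_on_axis(self):
        path = np.stack([np.linspace(0, 1, 100), np.zeros(100)], axis=1)
        ev = DetectionEvent(kind="correct", lags_ms=np.arange(100.0),
                            projection=path[:, 0], path_2d=path, item=0)
        H, xe, ye = spatial_histogram([ev], bins=20, extent=(-1, 2, -1, 1))
        assert H.sum() == 100
        # all mass in the y-bins straddling zero
        y_marginal = H.sum(axis=0)
        mid = len(y_marginal) // 2
        assert y_marginal[mid - 1:mid + 1].sum() == 100

    def test_mirror_symmetry(self):
        up = np.stack([np.linspace(0, 1, 50), np.linspace(0.03, 0.47, 50)],
                      axis=1)
        down = up * np.array([1.0, -1.0])
        evs = [DetectionEvent(kind="false", lags_ms=np.arange(50.0),
                              projection=p[:, 0], path_2d=p, item=0)
               for p in (up, down)]
        H, _, _ = spatial_histogram(evs, bins=20, extent=(-1, 2, -1, 1))
        assert np.array_equal(H, H[:, ::-1])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            spatial_histogram([])
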