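"""Mouse-trajectory trial scoring: reaches, completion, correctness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctmt.io import MouseTrajectory
from ctmt.performance import (
    PerformanceConfig,
    Reach,
    aggregate_performance,
    detect_reaches,
    evaluate_trial,
    split_terciles,
    trajectory_self_crossing,
    TrialResult,
)
from ctmt.stimuli import StimulusLayout


def traj(points, dt=10.0, button=True):
    pts = np.asarray(points, float)
    n = len(pts)
    return MouseTrajectory(t=np.arange(n) * dt, x=pts[:, 0], y=pts[:, 1],
                           button=np.full(n, button, bool))


def layout_at(positions, trial_type="A"):
    pos = np.asarray(positions, float)
    return StimulusLayout(positions=pos,
                          labels=[str(i + 1) for i in range(len(pos))],
                          trial_type=trial_type)


class TestDetectReaches:
    def test_close_approach_fires(self):
        lay = layout_at([(50, 50)])
        m = traj([(0, 41.0), (100, 41.0)])  # closest approach 9 px
        assert [r.item for r in detect_reaches(m, lay)] == [0]

    def test_out_of_radius_silent(self):
        lay = layout_at([(50, 50)])
        m = traj([(0, 39.5), (100, 39.5)])  # 10.5 px
        assert detect_reaches(m, lay) == []

    def test_fast_jump_across_circle(self):
        lay = layout_at([(50, 50)])
        m = traj([(0, 50), (100, 50)])  # segment passes through the centre
        assert [r.item for r in detect_reaches(m, lay)] == [0]

    def test_reentry_counts_twice(self):
        lay = layout_at([(50, 50)])
        m = traj([(50, 50), (50, 120), (50, 50), (50, 120)])
        assert [r.item for r in detect_reaches(m, lay)] == [0, 0]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_dense_resampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lay = layout_at(rng.uniform(0, 100, size=(3, 2)))
        pts = rng.uniform(0, 100, size=(6, 2))
        m = traj(pts)
        got = {r.item for r in detect_reaches(m, lay)}
        # oracle: resample each segment densely and test point distances
        oracle = set()
        for a, b in zip(pts[:-1], pts[1:]):
            for u in np.linspace(0, 1, 2001):
                p = a + u * (b - a)
                d = np.hypot(*(np.asarray(lay.positions) - p).T)
                oracle.update(np.flatnonzero(d <= 10.0).tolist())
        assert got == oracle


class TestEvaluateTrial:
    def _entries(self, items, dt=500.0):
        return [Reach(item=k, t_entry=i * dt, t_exit=i * dt + 50)
                for i, k in enumerate(items)]

    def _layout12(self):
        return layout_at([(i * 40, 0) for i in range(12)])

    def test_in_order_completion(self):
        lay = self._layout12()
        entries = self._entries(list(range(12)))
        res = evaluate_trial(entries, lay)
        assert res.completed and res.correct
        assert res.rt_s == pytest.approx(11 * 0.5)
        assert res.n_concatenated == 12

    def test_eleven_items_not_completed(self):
        res = evaluate_trial(self._entries(list(range(11))), self._layout12())
        assert not res.completed
        assert res.rt_s is None

    def test_wrong_item_then_corrected(self):
        seq = [0, 2, 1] + list(range(2, 12))  # touched 3 early, then fixed
        res = evaluate_trial(self._entries(seq), self._layout12())
        assert res.completed
        assert not res.correct

    def test_limit_censors(self):
        entries = self._entries(list(range(12)), dt=3000.0)  # 12th at 33 s
        res = evaluate_trial(entries, self._layout12())
        assert not res.completed

    def test_self_crossing_breaks_correctness(self):
        res = evaluate_trial(self._entries(list(range(12))), self._layout12(),
                             self_crossing=True)
        assert res.completed and not res.correct

    def test_require_correct_mode(self):
        cfg = PerformanceConfig(require_correct=True)
        res = evaluate_trial(self._entries([0, 2, 1] + list(range(2, 12))),
                             self._layout12(), cfg)
        assert not res.completed

    def test_completion_monotone_in_criterion(self):
        """Lowering the completion criterion never un-completes a trial."""
        entries = self._entries(list(range(10)))
        lay = layout_at([(i * 40, 0) for i in range(20)])
        done = [evaluate_trial(entries, lay, PerformanceConfig(completion_items=k)
                               ).completed for k in (12, 10, 8)]
        assert done == [False, True, True]


class TestSelfCrossing:
    def test_figure_eight(self):
        m = traj([(0, 0), (10, 10), (10, 0), (0, 10), (0, 0)])
        assert trajectory_self_crossing(m)

    def test_straight_path(self):
        m = traj([(0, 0), (5, 5), (10, 10)])
        assert not trajectory_self_crossing(m)

    def test_touching_at_one_point(self):
        m = traj([(0, 0), (10, 0), (10, 10), (5, 0), (5, -10)])
        assert trajectory_self_crossing(m)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.integers(0, 8, size=(6, 2)).astype(float)
        pts = pts[np.r_[True, np.any(np.diff(pts, axis=0) != 0, axis=1)]]
        if len(pts) < 3:
            return
        m = traj(pts)
        # oracle: any two non-adjacent segments closer than contact
        from shapely.geometry import LineString
        n = len(pts) - 1
        hit = False
        for i in range(n):
            for j in range(i + 1, n):
                inter = LineString(pts[i:i + 2]).intersection(LineString(pts[j:j + 2]))
                if inter.is_empty:
                    continue
                if j == i + 1 and inter.geom_type == "Point" \
                        and np.allclose([inter.x, inter.y], pts[j]):
                    continue  # adjacent segments legitimately share a vertex
                hit = True
        assert trajectory_self_crossing(m) == hit


class TestAggregates:
    def _res(self, tt, completed, rt=None):
        return TrialResult(entries=[], completed=completed,
                           correct=completed, rt_s=rt,
                           n_concatenated=12 if completed else 5,
                           self_crossing=False, trial_type=tt)

    def test_toy_completion_ratio(self):
        results = [self._res("A", True, 5.0), self._res("A", True, 6.0),
                   self._res("B", True, 8.0), self._res("B", False)]
        agg = aggregate_performance(results)
        assert agg["A"]["pc"] == 100.0
        assert agg["B"]["pc"] == 50.0
        assert agg["completion_ratio"] == pytest.approx(0.5)
        assert agg["rt_ratio"] == pytest.approx(8.0 / 5.5)

    def test_extreme_pc(self):
        assert aggregate_performance([self._res("A", True, 1.0)])["A"]["pc"] == 100.0
        assert aggregate_performance([self._res("A", False)])["A"]["pc"] == 0.0

    def test_zero_denominator_flagged(self):
        agg = aggregate_performance([self._res("A", False), self._res("B", True, 2.0)])
        assert agg["completion_ratio"] is None


class TestTerciles:
    @pytest.mark.parametrize("n, first, last", [
        (99, 33, 33), (100, 34, 33), (3, 1, 1), (101, 34, 33),
    ])
    def test_sizes(self, n, first, last):
        a, b = split_terciles(list(range(n)))
        assert (len(a), len(b)) == (first, last)
        assert a == list(range(first))
        assert b == list(range(n - last, n))

    def test_too_few(self):
        with pytest.raises(ValueError):
            split_terciles([1, 2])
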