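"""Constrained stimulus layouts for the computerised Trail Making Test.

Target arrangements are built one item at a time on a 30x30 pixel grid:
starting from a random node, each next node is proposed by independent
horizontal/vertical displacements whose magnitudes are Poisson(mu)
distributed (in grid units) with uniform random signs.  A proposal is
rejected if it falls off the grid, lands on an occupied node, or if the
straight stroke connecting it to the previous item crosses any earlier
stroke.  A finished 20-item layout is accepted only if the convex hull of
the item centres covers more than ``hull_min_fraction`` of the full grid
area; otherwise construction restarts.  Accepted layouts are labelled
either with numbers 1-20 (trial type A) or alternating numbers 1-10 and
letters A-J (trial type B).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "GridSpec",
    "StimulusLayout",
    "LayoutGenerationError",
    "strokes_cross",
    "hull_area_fraction",
    "generate_layout",
    "assign_labels",
    "generate_layout_set",
]

Point = tuple[float, float]
Segment = tuple[Point, Point]

#: Labels for a type-B trail: numbers 1-10 alternating with letters A-J.
_B_LABELS = [s for i in range(10) for s in (str(i + 1), chr(ord("A") + i))]


class LayoutGenerationError(RuntimeError):
    """Raised when the rejection-sampling budget of a stage is exhausted."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry and acceptance parameters of the stimulus grid.

    The defaults describe a 30x30 node lattice with 20 px spacing filling a
    600x600 px extent; items are circles of 10 px radius centred on nodes.
    """

    rows: int = 30
    cols: int = 30
    spacing_px: float = 20.0
    extent_px: float = 600.0
    item_radius_px: float = 10.0
    poisson_mu: float = 5.0
    hull_min_fraction: float = 0.40
    n_items: int = 20

    def __post_init__(self) -> None:
        if not math.isclose(self.rows * self.spacing_px, self.extent_px):
            raise ValueError("rows * spacing_px must equal extent_px")
        if not 0.0 < self.hull_min_fraction < 1.0:
            raise ValueError("hull_min_fraction must be in (0, 1)")
        if self.n_items < 3:
            raise ValueError("n_items must be at least 3")

    def node_to_px(self, node: tuple[int, int]) -> Point:
        """Pixel centre of grid node (col, row); origin top-left, y down."""
        return (
            (node[0] + 0.5) * self.spacing_px,
            (node[1] + 0.5) * self.spacing_px,
        )


@dataclass
class StimulusLayout:
    """An accepted trail layout: ordered item centres plus labelling."""

    positions: np.ndarray  # (n_items, 2) pixel coordinates, path order
    labels: list[str] = field(default_factory=list)
    trial_type: str | None = None  # "A" | "B" | None (unlabelled)
    hull_fraction: float = 0.0
    seed: int | None = None

    @property
    def n_items(self) -> int:
        return len(self.positions)

    def strokes(self) -> list[Segment]:
        """The n_items-1 straight strokes connecting consecutive centres."""
        pts = [tuple(p) for p in np.asarray(self.positions, float)]
        return [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]

    def to_dict(self) -> dict:
        return {
            "positions": np.asarray(self.positions, float).tolist(),
            "labels": list(self.labels),
            "trial_type": self.trial_type,
            "hull_fraction": self.hull_fraction,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusLayout":
        return cls(
            positions=np.asarray(d["positions"], float),
            labels=list(d.get("labels", [])),
            trial_type=d.get("trial_type"),
            hull_fraction=float(d.get("hull_fraction", 0.0)),
            seed=d.get("seed"),
        )

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"coordinate_convention": "origin top-left, y increases downward",
                 **self.to_dict()},
                fh,
                indent=1,
            )

    @classmethod
    def read_json(cls, path) -> "StimulusLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# exact segment-intersection predicate
# ---------------------------------------------------------------------------

def _orient(a: Point, b: Point, c: Point) -> float:
    """Signed twice-area of triangle abc; exact for integer coordinates."""
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def _on_segment(a: Point, b: Point, p: Point) -> bool:
    """p collinear with ab assumed; True if p lies within the bounding box."""
    return (
        min(a[0], b[0]) <= p[0] <= max(a[0], b[0])
        and min(a[1], b[1]) <= p[1] <= max(a[1], b[1])
    )


def _segments_intersect(p1: Point, p2: Point, p3: Point, p4: Point) -> bool:
    """True iff closed segments p1p2 and p3p4 share at least one point."""
    d1 = _orient(p3, p4, p1)
    d2 = _orient(p3, p4, p2)
    d3 = _orient(p1, p2, p3)
    d4 = _orient(p1, p2, p4)
    if ((d1 > 0) != (d2 > 0)) and d1 != 0 and d2 != 0 \
            and ((d3 > 0) != (d4 > 0)) and d3 != 0 and d4 != 0:
        return True
    if d1 == 0 and _on_segment(p3, p4, p1):
        return True
    if d2 == 0 and _on_segment(p3, p4, p2):
        return True
    if d3 == 0 and _on_segment(p1, p2, p3):
        return True
    if d4 == 0 and _on_segment(p1, p2, p4):
        return True
    return False


def strokes_cross(s1: Segment, s2: Segment) -> bool:
    """Do two trail strokes cross?

    Proper intersections and collinear overlaps count as crossings.
    Segments that share exactly one endpoint -- consecutive strokes of the
    trail, which meet at an item by construction -- do not, unless they
    additionally overlap collinearly (a doubled-back stroke).

    Raises ``ValueError`` for zero-length segments.
    """
    (a, b), (c, d) = (tuple(map(tuple, s1)), tuple(map(tuple, s2)))
    if a == b or c == d:
        raise ValueError("degenerate zero-length segment")
    shared = [p for p in (a, b) if p in (c, d)]
    if len(shared) == 2:
        return True  # identical or reversed segment: full overlap
    if len(shared) == 1:
        # allowed shared item; cross only if overlap extends beyond the point
        oth1 = b if a == shared[0] else a
        oth2 = d if c == shared[0] else c
        if _orient(c, d, oth1) == 0 and _on_segment(c, d, oth1):
            return True
        if _orient(a, b, oth2) == 0 and _on_segment(a, b, oth2):
            return True
        return False
    return _segments_intersect(a, b, c, d)


def hull_area_fraction(positions: Sequence[Point] | np.ndarray,
                       grid: GridSpec) -> float:
    """Convex-hull area of the item centres over the full grid area.

    Fewer than three non-collinear points span zero area and return 0.
    """
    pts = np.atleast_2d(np.asarray(positions, float))
    if pts.size == 0:
        raise ValueError("hull_area_fraction requires at least one point")
    if len(pts) < 3:
        return 0.0
    try:
        area = ConvexHull(pts).volume  # in 2-D, .volume is the area
    except QhullError:
        return 0.0  # collinear / degenerate point set
    return float(area) / grid.extent_px**2


# ---------------------------------------------------------------------------
# sequential construction with rejection
# ---------------------------------------------------------------------------

def _build_path_nodes(grid: GridSpec, rng: np.random.Generator,
                      max_step_retries: int) -> list[tuple[int, int]] | None:
    """One attempt at a full non-crossing node path; None on dead end."""
    start = (int(rng.integers(0, grid.cols)), int(rng.integers(0, grid.rows)))
    nodes = [start]
    occupied = {start}
    strokes: list[Segment] = []
    while len(nodes) < grid.n_items:
        cur = nodes[-1]
        for _ in range(max_step_retries):
            dx = int(rng.poisson(grid.poisson_mu))
            dy = int(rng.poisson(grid.poisson_mu))
            if dx == 0 and dy == 0:
                continue  # zero net displacement: resample
            if rng.random() < 0.5:
                dx = -dx
            if rng.random() < 0.5:
                dy = -dy
            nxt = (cur[0] + dx, cur[1] + dy)
            if not (0 <= nxt[0] < grid.cols and 0 <= nxt[1] < grid.rows):
                continue
            if nxt in occupied:
                continue
            stroke: Segment = (cur, nxt)
            if any(strokes_cross(stroke, s) for s in strokes):
                continue
            nodes.append(nxt)
            occupied.add(nxt)
            strokes.append(stroke)
            break
        else:
            return None  # dead end: restart the whole layout
    return nodes


def generate_layout(grid: GridSpec, seed: int, *,
                    max_step_retries: int = 200,
                    max_restarts: int = 5000) -> StimulusLayout:
    """Generate one accepted (unlabelled) layout, deterministic under seed.

    The whole construction restarts whenever a step dead-ends or the
    finished path fails the hull-coverage filter.  Raises
    :class:`LayoutGenerationError` if the restart budget is exhausted.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        nodes = _build_path_nodes(grid, rng, max_step_retries)
        if nodes is None:
            continue
        pts = np.array([grid.node_to_px(n) for n in nodes])
        frac = hull_area_fraction(pts, grid)
        if frac > grid.hull_min_fraction:
            return StimulusLayout(positions=pts, hull_fraction=frac, seed=seed)
    raise LayoutGenerationError(
        f"no acceptable layout within {max_restarts} restarts "
        f"(hull filter {grid.hull_min_fraction:.2f})"
    )


def assign_labels(layout: StimulusLayout, trial_type: str) -> StimulusLayout:
    """Label the path in order: type A -> "1".."20"; type B -> 1,A,2,B,...,10,J.

    Returns a new layout; the 20-item schemes require exactly 20 positions.
    """
    if trial_type not in ("A", "B"):
        raise ValueError(f"trial_type must be 'A' or 'B', got {trial_type!r}")
    if layout.n_items != 20:
        raise ValueError(
            f"20-item label scheme needs 20 positions, layout has {layout.n_items}"
        )
    labels = [str(i + 1) for i in range(20)] if trial_type == "A" else list(_B_LABELS)
    return StimulusLayout(
        positions=np.array(layout.positions, float, copy=True),
        labels=labels,
        trial_type=trial_type,
        hull_fraction=layout.hull_fraction,
        seed=layout.seed,
    )


def generate_layout_set(grid: GridSpec, n_layouts: int, seed: int,
                        ) -> tuple[list[StimulusLayout], dict]:
    """Generate ``n_layouts`` accepted layouts plus hull-coverage summary.

    Each layout gets its own child seed derived from ``seed`` so the set is
    reproducible as a whole.  The summary reports mean/sd/min/max of the
    hull fractions (sd is NaN and flagged for a single layout).
    """
    if n_layouts < 1:
        raise ValueError("n_layouts must be >= 1")
    root = np.random.SeedSequence(seed)
    layouts = [
        generate_layout(grid, int(child.generate_state(1)[0] % 2**31))
        for child in root.spawn(n_layouts)
    ]
    fracs = np.array([lay.hull_fraction for lay in layouts])
    summary = {
        "n": n_layouts,
        "mean_hull_fraction": float(fracs.mean()),
        "sd_hull_fraction": float(fracs.std(ddof=1)) if n_layouts > 1 else float("nan"),
        "sd_defined": n_layouts > 1,
        "min_hull_fraction": float(fracs.min()),
        "max_hull_fraction": float(fracs.max()),
    }
    return layouts, summary
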