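"""Data containers and file plumbing for cTMT sessions.

Coordinate convention throughout the package: pixel coordinates with the
origin at the top-left of the screen and y increasing downward.  Gaze is
sampled nominally at 1 kHz with a per-sample validity flag; the mouse log
is irregular because the cursor position is recorded only while it moves,
so the cursor position at an arbitrary time is defined by zero-order hold
(the most recent logged sample).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GazeRecording",
    "MouseTrajectory",
    "TrialEntry",
    "SessionManifest",
    "read_gaze",
    "write_gaze",
    "read_mouse",
    "write_mouse",
    "assemble_session",
]

#: Runs of invalid/missing gaze longer than this are materialised as gaps
#: (consumed by blink handling downstream).
GAP_THRESHOLD_MS = 20.0


@dataclass
class GazeRecording:
    """Raw gaze samples: strictly increasing timestamps (ms), pixels."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.valid = np.asarray(self.valid, bool)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.valid)):
            raise ValueError("gaze arrays must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            i = int(np.argmax(np.diff(self.t) <= 0))
            raise ValueError(f"gaze timestamps not strictly increasing at row {i + 1}")
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad):
            raise ValueError("non-finite coordinates flagged valid")

    def __len__(self) -> int:
        return len(self.t)

    def gaps(self, threshold_ms: float = GAP_THRESHOLD_MS) -> list[tuple[float, float]]:
        """(start, end) time spans of invalid/missing data longer than threshold.

        Covers both runs of invalid samples and holes in the timestamp grid.
        """
        if len(self.t) == 0:
            return []
        spans: list[tuple[float, float]] = []
        # runs of invalid samples
        inval = ~self.valid
        if np.any(inval):
            edges = np.flatnonzero(np.diff(np.r_[0, inval.view(np.int8), 0]))
            for s, e in zip(edges[::2], edges[1::2]):
                t0, t1 = self.t[s], self.t[e - 1]
                if t1 - t0 >= threshold_ms or (e - s) >= threshold_ms:
                    spans.append((float(t0), float(t1)))
        # holes in the sampling grid
        dt = np.diff(self.t)
        for i in np.flatnonzero(dt > threshold_ms):
            spans.append((float(self.t[i]), float(self.t[i + 1])))
        return sorted(spans)


@dataclass
class MouseTrajectory:
    """Irregularly sampled cursor log with button state.

    ``position_at`` implements the zero-order-hold semantics: between two
    logged samples the cursor sits at the earlier one.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    button: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.button = np.asarray(self.button, bool)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.button)):
            raise ValueError("mouse arrays must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) < 0):
            i = int(np.argmax(np.diff(self.t) < 0))
            raise ValueError(f"mouse timestamps decrease at row {i + 1}")

    def __len__(self) -> int:
        return len(self.t)

    def position_at(self, t) -> np.ndarray:
        """Cursor position at time(s) ``t`` by zero-order hold.

        Queries before the first sample return the first sample's position.
        """
        if len(self.t) == 0:
            raise ValueError("empty trajectory")
        idx = np.searchsorted(self.t, np.asarray(t, float), side="right") - 1
        idx = np.clip(idx, 0, len(self.t) - 1)
        return np.stack([self.x[idx], self.y[idx]], axis=-1)

    def press_time(self) -> float:
        """Timestamp of the first sample with the button held."""
        held = np.flatnonzero(self.button)
        if held.size == 0:
            raise ValueError("button never pressed")
        return float(self.t[held[0]])

    def release_time(self) -> float:
        """Timestamp of the last sample with the button held."""
        held = np.flatnonzero(self.button)
        if held.size == 0:
            raise ValueError("button never pressed")
        return float(self.t[held[-1]])


@dataclass
class TrialEntry:
    """One row of a session manifest."""

    layout: str  # path to layout JSON
    trial_type: str
    block: int  # 1-based block index
    gaze: str  # path to gaze CSV
    mouse: str  # path to mouse CSV


@dataclass
class SessionManifest:
    """A participant's session: ordered trials plus optional external scores."""

    participant: str
    trials: list[TrialEntry]
    ifs_total: float | None = None
    cdt_table: list[dict] | None = None  # rows: {"set_size": 4|6, "correct": bool}
    warnings: list[str] = field(default_factory=list)


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_gaze(path, dialect: str = "csv") -> GazeRecording:
    """Read gaze samples from CSV ``t,x,y[,valid]`` or a minimal ASC-like dialect.

    The ASC-like dialect is whitespace-separated ``t x y`` sample lines;
    lines whose x/y fields are '.' (tracker signal loss) become invalid
    samples.  Structural violations raise with the offending row.
    """
    if dialect == "csv":
        df = _read_csv(path, ["t", "x", "y"])
        valid = (
            df["valid"].astype(bool).to_numpy()
            if "valid" in df.columns
            else np.isfinite(df["x"].to_numpy(float)) & np.isfinite(df["y"].to_numpy(float))
        )
        x = df["x"].to_numpy(float)
        y = df["y"].to_numpy(float)
    elif dialect == "asc":
        t_l, x_l, y_l, v_l = [], [], [], []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                parts = line.split()
                if not parts or not parts[0].replace(".", "", 1).isdigit():
                    continue  # header / message line
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: malformed sample line")
                t_l.append(float(parts[0]))
                lost = parts[1] == "." or parts[2] == "."
                x_l.append(np.nan if lost else float(parts[1]))
                y_l.append(np.nan if lost else float(parts[2]))
                v_l.append(not lost)
        df = pd.DataFrame({"t": t_l})
        x, y, valid = np.array(x_l), np.array(y_l), np.array(v_l)
    else:
        raise ValueError(f"unknown gaze dialect {dialect!r}")
    t = df["t"].to_numpy(float)
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(f"{path}: non-monotone timestamp at row {int(bad[0]) + 2}")
    return GazeRecording(t=t, x=np.where(valid, x, np.nan),
                         y=np.where(valid, y, np.nan), valid=valid)


def write_gaze(rec: GazeRecording, path) -> None:
    pd.DataFrame({"t": rec.t, "x": rec.x, "y": rec.y,
                  "valid": rec.valid.astype(int)}).to_csv(path, index=False)


def read_mouse(path) -> MouseTrajectory:
    """Read a mouse log CSV with columns ``t,x,y,button``."""
    df = _read_csv(path, ["t", "x", "y", "button"])
    return MouseTrajectory(
        t=df["t"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        button=df["button"].to_numpy().astype(bool),
    )


def write_mouse(traj: MouseTrajectory, path) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y,
                  "button": traj.button.astype(int)}).to_csv(path, index=False)


def assemble_session(manifest_path, *, strict: bool = False) -> SessionManifest:
    """Load a session manifest JSON and validate its structure.

    A complete session has 5 blocks of 20 trials with strictly alternating
    A/B types.  Violations are reported as warnings on the returned object
    (and via ``warnings.warn``), never silently repaired; dangling file
    references are errors.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        raw = json.load(fh)
    trials = [TrialEntry(**tr) for tr in raw["trials"]]
    base = manifest_path.parent
    for tr in trials:
        for ref in (tr.layout, tr.gaze, tr.mouse):
            if not (base / ref).exists():
                raise FileNotFoundError(f"manifest references missing file: {ref}")
    msgs: list[str] = []
    types = [tr.trial_type for tr in trials]
    for i in range(1, len(types)):
        if types[i] == types[i - 1]:
            msgs.append(f"trial types do not alternate at trial {i + 1}")
    blocks = sorted({tr.block for tr in trials})
    if blocks != [1, 2, 3, 4, 5]:
        msgs.append(f"expected 5 blocks, found {blocks}")
    else:
        for b in blocks:
            n = sum(tr.block == b for tr in trials)
            if n != 20:
                msgs.append(f"block {b} has {n} trials, expected 20")
    for m in msgs:
        warnings.warn(m, stacklevel=2)
    if strict and msgs:
        raise ValueError("; ".join(msgs))
    return SessionManifest(
        participant=str(raw.get("participant", manifest_path.stem)),
        trials=trials,
        ifs_total=raw.get("ifs_total"),
        cdt_table=raw.get("cdt_table"),
        warnings=msgs,
    )
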