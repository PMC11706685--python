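"""Reading and writing digitized root centerline traces.

A trace is an ordered polyline of (x, y) coordinates in centimetres,
base-first: the first point is the root-hypocotyl junction (the basal
point) and the last point is the root tip.  The internal frame is y-up
with gravity pointing toward decreasing y, so "downward" growth has a
single sign convention everywhere.  Image-style y-down exports are
flipped at read time; unit conversion (pixels -> cm) also happens only
at the I/O boundary.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTraceError,
    ParameterError,
    SchemaError,
    TraceParseError,
)

logger = logging.getLogger(__name__)

DEFAULT_GRAVITY = np.array([0.0, -1.0])

TRACE_TABLE_COLUMNS = ["root_id", "group", "point_index", "x", "y"]


def collapse_duplicate_points(points: np.ndarray, root_id: str = "?") -> np.ndarray:
    """Drop consecutive duplicate points (zero-length segments).

    Manual clicking occasionally produces repeated coordinates; they are
    collapsed with a warning rather than rejected.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise DegenerateTraceError(
            f"trace {root_id!r}: expected an (n, 2) coordinate array, got shape {points.shape}"
        )
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 0.0])
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "trace %s: collapsed %d consecutive duplicate point(s)", root_id, n_dropped
        )
    return points[keep]


@dataclass
class RootTrace:
    """Ordered 2D root centerline, base-first, coordinates in cm."""

    root_id: str
    points: np.ndarray
    group: str = ""
    scale_applied: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise DegenerateTraceError(
                f"trace {self.root_id!r}: expected an (n, 2) array, got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise DegenerateTraceError(f"trace {self.root_id!r}: non-finite coordinates")
        if self.n_points < 3:
            raise DegenerateTraceError(
                f"trace {self.root_id!r}: needs at least 3 distinct points, got {self.n_points}"
            )
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise DegenerateTraceError(
                f"trace {self.root_id!r}: contains zero-length segments "
                "(collapse duplicates before constructing)"
            )

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def base(self) -> np.ndarray:
        return self.points[0]

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class TraceCollection:
    """A set of traces with a common gravity convention."""

    traces: list[RootTrace]
    gravity_direction: np.ndarray = field(
        default_factory=lambda: DEFAULT_GRAVITY.copy()
    )
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gravity_direction = np.asarray(self.gravity_direction, dtype=float)
        if self.gravity_direction.shape != (2,):
            raise ParameterError("gravity_direction must be a 2-vector")
        if abs(np.linalg.norm(self.gravity_direction) - 1.0) > 1e-9:
            raise ParameterError("gravity_direction must have unit norm (tol 1e-9)")
        ids = [t.root_id for t in self.traces]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate root_id(s) in collection: {dup}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.traces:
            seen.setdefault(t.group, None)
        return list(seen)


def _parse_xy_lines(lines: Sequence[str], path: str) -> np.ndarray:
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            if lineno == 1 and not rows:
                continue  # header row auto-detected by non-numeric first line
            raise TraceParseError(f"{path}: non-numeric row at line {lineno}: {line!r}")
        if len(vals) < 2:
            raise TraceParseError(
                f"{path}: expected two columns at line {lineno}: {line!r}"
            )
        rows.append((vals[0], vals[1]))
    if not rows:
        raise TraceParseError(f"{path}: no coordinate rows found")
    return np.array(rows, dtype=float)


def read_xy_trace(
    path: str | Path,
    scale_cm_per_unit: float,
    y_axis: str = "up",
    root_id: str | None = None,
    group: str = "",
) -> RootTrace:
    """Read a two-column XY coordinate export (ImageJ/Fiji dialect).

    Accepts whitespace- or comma-delimited numeric text with an optional
    header row.  Coordinates are multiplied by ``scale_cm_per_unit``; for
    ``y_axis="down"`` (image convention) the y coordinate is negated so
    the internal frame is y-up.  Base-first ordering is preserved as given.
    """
    if scale_cm_per_unit <= 0:
        raise ParameterError("scale_cm_per_unit must be positive")
    if y_axis not in ("up", "down"):
        raise ParameterError("y_axis must be 'up' or 'down'")
    path = Path(path)
    pts = _parse_xy_lines(path.read_text().splitlines(), str(path))
    pts = pts * scale_cm_per_unit
    if y_axis == "down":
        pts[:, 1] = -pts[:, 1]
    rid = root_id if root_id is not None else path.stem
    pts = collapse_duplicate_points(pts, rid)
    if pts.shape[0] < 3:
        raise DegenerateTraceError(
            f"trace {rid!r}: fewer than 3 distinct points after collapsing duplicates"
        )
    return RootTrace(root_id=rid, points=pts, group=group, scale_applied=True)


def read_trace_table(
    path: str | Path | io.IOBase,
    scale_cm_per_unit: float = 1.0,
    gravity_direction: np.ndarray | None = None,
) -> TraceCollection:
    """Read a long-format trace table (root_id, group, point_index, x, y)."""
    if scale_cm_per_unit <= 0:
        raise ParameterError("scale_cm_per_unit must be positive")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty trace table")
    missing = [c for c in TRACE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df.duplicated(subset=["root_id", "point_index"]).any():
        bad = df[df.duplicated(subset=["root_id", "point_index"])]["root_id"].unique()
        raise SchemaError(f"{path}: duplicated (root_id, point_index) for {list(bad)}")
    traces = []
    for rid, sub in df.groupby("root_id", sort=False):
        sub = sub.sort_values("point_index")
        pts = sub[["x", "y"]].to_numpy(dtype=float) * scale_cm_per_unit
        group = str(sub["group"].iloc[0])
        pts = collapse_duplicate_points(pts, str(rid))
        traces.append(RootTrace(root_id=str(rid), points=pts, group=group))
    grav = DEFAULT_GRAVITY if gravity_direction is None else gravity_direction
    return TraceCollection(
        traces=traces,
        gravity_direction=grav,
        provenance={"source": str(path), "scale_cm_per_unit": scale_cm_per_unit},
    )


def write_traces(collection: TraceCollection, path: str | Path) -> None:
    """Write a collection in the long-format trace-table schema."""
    frames = []
    for t in collection:
        frames.append(
            pd.DataFrame(
                {
                    "root_id": t.root_id,
                    "group": t.group,
                    "point_index": np.arange(t.n_points),
                    "x": t.points[:, 0],
                    "y": t.points[:, 1],
                }
            )
        )
    if not frames:
        raise SchemaError("cannot write an empty trace collection")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


RESULT_COLUMNS = [
    "root_id",
    "group",
    "L",
    "Lx",
    "Ly",
    "Lc",
    "HGI",
    "VGI",
    "SI",
    "ci_mean",
    "ci_max",
    "n_exceed",
    "ci_0_0.5",
    "ci_0.5_1",
    "ci_1_inf",
    "tip_angle_deg",
]


def write_results(indices: Sequence, path: str | Path) -> None:
    """Write per-root results, one row per root, fixed column order."""
    if not indices:
        raise SchemaError("cannot write an empty results list")
    rows = [ri.to_dict() if hasattr(ri, "to_dict") else dict(ri) for ri in indices]
    df = pd.DataFrame(rows)
    cols = [c for c in RESULT_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in RESULT_COLUMNS
    ]
    df[cols].to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a per-root results table back into a DataFrame."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty results table")
    if "root_id" not in df.columns:
        raise SchemaError(f"{path}: not a results table (no root_id column)")
    return df
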