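"""Reading and writing pose-trajectory tables and result tables.

The raw input is a per-frame table of (x, y, likelihood) triplets for
every tracked landmark, in either of the two dialects markerless
tracking software commonly emits:

* flat CSV with a three-level column header (scorer / landmark /
  {x, y, likelihood}) and the frame index in the first column;
* an HDF5 container holding the same pandas DataFrame.

Both are normalized into a :class:`TrajectoryTable`, the package's
in-memory container: dense ``(n_frames, n_landmarks)`` arrays for x, y
and likelihood plus a boolean validity mask.

Event and feature outputs are plain tab-separated text with a
commented header block documenting units, and round-trip exactly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ChamberLayout

__all__ = [
    "TrajectoryTable",
    "read_pose_table",
    "write_pose_table",
    "split_chambers",
    "write_events",
    "read_events",
    "write_features",
    "read_features",
]


@dataclass
class TrajectoryTable:
    """Per-frame landmark coordinates and likelihoods for one chamber.

    Arrays are shaped ``(n_frames, n_landmarks)``; column order follows
    ``landmarks``. ``valid`` marks frames whose coordinates are finite
    and whose likelihood is present; downstream filters refine it.
    """

    landmarks: list[str]
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    fps: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n, m = self.x.shape
        if n < 1:
            raise ValueError("trajectory table needs n_frames >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if m != len(self.landmarks):
            raise ValueError("landmark list does not match array width")
        for name, arr in (("y", self.y), ("likelihood", self.likelihood)):
            if arr.shape != (n, m):
                raise ValueError(f"{name} shape {arr.shape} != {(n, m)}")
        finite_lik = np.isfinite(self.likelihood)
        if np.any((self.likelihood < 0) | (self.likelihood > 1), where=finite_lik):
            raise ValueError("likelihoods must lie in [0, 1]")
        if self.valid is None:
            self.valid = (
                np.isfinite(self.x)
                & np.isfinite(self.y)
                & finite_lik
            )
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (n, m):
                raise ValueError("validity mask shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    def index(self, landmark: str) -> int:
        try:
            return self.landmarks.index(landmark)
        except ValueError:
            raise KeyError(f"landmark {landmark!r} not found") from None

    def has_landmark(self, landmark: str) -> bool:
        return landmark in self.landmarks

    def xy(self, landmark: str) -> np.ndarray:
        """(n_frames, 2) coordinate array for one landmark."""
        j = self.index(landmark)
        return np.column_stack([self.x[:, j], self.y[:, j]])

    def copy(self) -> "TrajectoryTable":
        return TrajectoryTable(
            landmarks=list(self.landmarks),
            x=self.x.copy(),
            y=self.y.copy(),
            likelihood=self.likelihood.copy(),
            fps=self.fps,
            valid=self.valid.copy(),
        )

    def subset(self, landmarks: Sequence[str]) -> "TrajectoryTable":
        idx = [self.index(lm) for lm in landmarks]
        return TrajectoryTable(
            landmarks=list(landmarks),
            x=self.x[:, idx],
            y=self.y[:, idx],
            likelihood=self.likelihood[:, idx],
            fps=self.fps,
            valid=self.valid[:, idx],
        )

    def to_dataframe(self, scorer: str = "stairreach") -> pd.DataFrame:
        cols = pd.MultiIndex.from_product(
            [[scorer], self.landmarks, ["x", "y", "likelihood"]],
            names=["scorer", "bodyparts", "coords"],
        )
        data = np.empty((self.n_frames, 3 * len(self.landmarks)))
        for j in range(len(self.landmarks)):
            data[:, 3 * j] = self.x[:, j]
            data[:, 3 * j + 1] = self.y[:, j]
            data[:, 3 * j + 2] = self.likelihood[:, j]
        return pd.DataFrame(data, columns=cols)


def _table_from_dataframe(df: pd.DataFrame, fps: float) -> TrajectoryTable:
    if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels < 2:
        raise ValueError("pose table must have a multi-level column header")
    # drop the scorer level if present (3 levels: scorer/bodyparts/coords)
    if df.columns.nlevels == 3:
        df = df.droplevel(0, axis=1)
    landmarks = list(dict.fromkeys(df.columns.get_level_values(0)))
    n = len(df)
    m = len(landmarks)
    x = np.full((n, m), np.nan)
    y = np.full((n, m), np.nan)
    lik = np.full((n, m), np.nan)
    for j, lm in enumerate(landmarks):
        sub = df[lm]
        for coord, target in (("x", x), ("y", y), ("likelihood", lik)):
            if coord not in sub.columns:
                raise ValueError(f"landmark {lm!r} missing {coord!r} column")
            col = pd.to_numeric(sub[coord], errors="coerce")
            bad = col.isna() & sub[coord].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric value in {lm}/{coord} at row {row}"
                )
            target[:, j] = col.to_numpy(dtype=float)
    return TrajectoryTable(landmarks=landmarks, x=x, y=y, likelihood=lik, fps=fps)


def read_pose_table(
    path: str | Path,
    layout: ChamberLayout | None = None,
    *,
    fps: float | None = None,
) -> TrajectoryTable:
    """Read a pose table (CSV with 3-level header, or HDF5).

    When ``layout`` is given, its landmarks are required to be present
    (a missing one is a hard error naming it) and its frame rate is
    used unless ``fps`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fps is None:
        fps = layout.fps if layout is not None else 100.0
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        df = pd.read_hdf(path)
    else:
        if path.stat().st_size == 0:
            raise ValueError(f"{path}: empty pose table")
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        if len(df) == 0:
            raise ValueError(f"{path}: pose table has no frames")
    table = _table_from_dataframe(df, fps=fps)
    if layout is not None:
        for lm in layout.required_landmarks():
            if not table.has_landmark(lm):
                raise ValueError(f"landmark {lm} not found in {path}")
    return table


def write_pose_table(
    table: TrajectoryTable, path: str | Path, scorer: str = "stairreach"
) -> None:
    path = Path(path)
    df = table.to_dataframe(scorer=scorer)
    if path.suffix in (".h5", ".hdf5", ".hdf"):
        df.to_hdf(path, key="poses", mode="w")
    else:
        df.to_csv(path, index_label="frame")


def split_chambers(
    global_table: TrajectoryTable,
    offsets: Sequence[tuple[float, float]],
    landmark_groups: Sequence[Sequence[str]] | None = None,
    *,
    frame_size: tuple[int, int] = (640, 480),
    chamber_size: tuple[int, int] = (320, 240),
) -> list[TrajectoryTable]:
    """Split a multi-chamber table into per-chamber local-coordinate tables.

    Each chamber's coordinates are translated by its crop origin
    (global minus offset). ``landmark_groups`` selects which landmarks
    belong to each chamber; by default every chamber keeps all
    landmarks. Landmarks falling outside their chamber on more than
    half of the valid frames trigger a warning, not an error: tracking
    glitches should not abort a session.
    """
    import warnings

    w, h = frame_size
    cw, ch = chamber_size
    out = []
    for k, (ox, oy) in enumerate(offsets):
        if not (0 <= ox <= w - cw and 0 <= oy <= h - ch):
            raise ValueError(f"offset {(ox, oy)} outside the {w}x{h} frame")
        names = (
            list(landmark_groups[k])
            if landmark_groups is not None
            else list(global_table.landmarks)
        )
        sub = global_table.subset(names)
        local = sub.copy()
        local.x = sub.x - ox
        local.y = sub.y - oy
        for j, lm in enumerate(local.landmarks):
            v = local.valid[:, j]
            if not v.any():
                continue
            inside = (
                (local.x[v, j] >= 0)
                & (local.x[v, j] < cw)
                & (local.y[v, j] >= 0)
                & (local.y[v, j] < ch)
            )
            if inside.mean() < 0.5:
                warnings.warn(
                    f"chamber {k}: landmark {lm} outside the chamber on "
                    f"{100 * (1 - inside.mean()):.0f}% of valid frames",
                    stacklevel=2,
                )
        out.append(local)
    return out


# ---------------------------------------------------------------------------
# events / features tables
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    ("side", "str", "body side (left/right)"),
    ("kind", "str", "event kind (reach/slip)"),
    ("start", "int", "first frame of the event (0-based, inclusive)"),
    ("inversion", "int", "turning-point frame (reach only; -1 if n/a)"),
    ("end", "int", "one past the last frame (half-open window)"),
    ("displacement_ratio", "float", "mean |dx| / mean |dy| (dimensionless)"),
    ("peak_speed", "float", "peak frame-to-frame speed (px/frame)"),
    ("target_well", "int", "nearest well at inversion, 1..8 (-1 if n/a)"),
    ("target_emptied", "int", "1 if the target well was already emptied"),
    ("outcome", "str", "no_contact/success/drop (reach) or n/a"),
    ("removal_frame", "int", "confirmed pellet-removal frame (-1 if none)"),
    ("drop_frame", "int", "pellet-drop frame (-1 if none)"),
]


def _write_commented_table(
    df: pd.DataFrame, path: str | Path, header_lines: Iterable[str]
) -> None:
    path = Path(path)
    buf = _io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    path.write_text(buf.getvalue())


def write_events(events_df: pd.DataFrame, path: str | Path) -> None:
    """Write an events table (TSV with a commented unit header).

    Expects one row per detected event, sorted by start frame, with the
    documented column set; extra columns are preserved.
    """
    if len(events_df) and not events_df["start"].is_monotonic_increasing:
        events_df = events_df.sort_values("start", kind="stable")
    header = ["stairreach events table", "columns:"]
    header += [f"  {n} [{t}]: {doc}" for n, t, doc in _EVENT_COLUMNS]
    cols = [c for c, _, _ in _EVENT_COLUMNS]
    extra = [c for c in events_df.columns if c not in cols]
    df = events_df.reindex(columns=cols + extra)
    _write_commented_table(df, path, header)


def read_events(path: str | Path) -> pd.DataFrame:
    # "n/a" is a literal outcome marker, not a missing value
    df = pd.read_csv(
        path, sep="\t", comment="#", keep_default_na=False, na_values=[""]
    )
    if len(df) == 0:
        return pd.DataFrame(columns=[c for c, _, _ in _EVENT_COLUMNS])
    for col, typ, _ in _EVENT_COLUMNS:
        if typ == "int" and col in df:
            df[col] = df[col].astype(int)
    return df


def write_features(features_df: pd.DataFrame, path: str | Path) -> None:
    """Write the per-side session feature table (TSV).

    One row per (session, side); identifier columns followed by the 30
    outcome parameters. Missing kinematics are empty cells, not zeros.
    """
    header = [
        "stairreach session features",
        "one row per session side; 30 outcome parameters after identifiers",
        "units: distances cm, durations s, velocities cm/s, "
        "accelerations cm/s^2, counts dimensionless",
    ]
    _write_commented_table(features_df, path, header)


def read_features(path: str | Path) -> pd.DataFrame:
    # identifiers like "NA" are strings, not missing values
    return pd.read_csv(
        path, sep="\t", comment="#", keep_default_na=False, na_values=[""]
    )
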