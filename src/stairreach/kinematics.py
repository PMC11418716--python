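"""Per-event kinematics, the success coefficient, and the 30-parameter
per-side session feature table.

All kinematic quantities are Euclidean metrics computed on the cleaned
2D paw trajectory, converted from pixels and frames to centimetres and
seconds with the chamber scale and frame rate (Δt = 1/fps, 10 ms at
100 Hz):

* path length  ``s = Σ sqrt(Δx² + Δy²) / px_per_cm``
* speed        ``v[f] = sqrt(Δx² + Δy²) / (px_per_cm · Δt)``
* acceleration ``a[f] = Δv / Δt``  (signed)

Each reaching attempt is scored over three scopes — the full attempt,
the reach phase (start to inversion) and the retraction phase
(inversion to end) — with eight summaries per scope: distance,
duration, mean velocity, mean acceleration, and min/max of the
instantaneous velocity and acceleration. With the five event-count
parameters (success coefficient, success / pellet / reach / slip
events) and the session-mean slip depth this yields the 30-parameter
outcome set per body side.

The success coefficient rewards retrieving many pellets in few
attempts::

    k_success = reaches_successful**2 / reaches_all

where ``reaches_all`` counts only reaches toward wells not yet emptied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ChamberLayout
from .events import MotionEvent
from .pellets import PelletSignal, ReachOutcome
from .preprocess import CleanTrajectory

__all__ = [
    "KinematicFeatures",
    "OutcomeCounts",
    "SCOPES",
    "KIN_FIELDS",
    "FEATURE_COLUMNS",
    "path_length",
    "speed_profile",
    "acceleration_profile",
    "event_kinematics",
    "slip_depth",
    "success_coefficient",
    "session_features",
    "normalized_to_baseline",
]

SCOPES = ("attempt", "reach", "retraction")
KIN_FIELDS = (
    "distance_cm",
    "duration_s",
    "velocity_mean",
    "acceleration_mean",
    "velocity_min",
    "velocity_max",
    "acceleration_min",
    "acceleration_max",
)

COUNT_COLUMNS = (
    "k_success",
    "success_events",
    "pellet_events",
    "reach_events",
    "slip_events",
)

#: the 30 outcome parameters, in output order
FEATURE_COLUMNS = (
    list(COUNT_COLUMNS)
    + [f"{scope}_{fieldname}" for scope in SCOPES for fieldname in KIN_FIELDS]
    + ["slip_depth_cm"]
)
assert len(FEATURE_COLUMNS) == 30

ID_COLUMNS = ("animal", "session", "day", "side")


@dataclass
class KinematicFeatures:
    """Eight kinematic summaries for each of the three scopes."""

    per_scope: dict[str, dict[str, float]]

    def flat(self) -> dict[str, float]:
        return {
            f"{scope}_{k}": v
            for scope in SCOPES
            for k, v in self.per_scope[scope].items()
        }


@dataclass
class OutcomeCounts:
    """Event-count outcome parameters for one side of one session."""

    reaches_all: int
    reaches_successful: int
    pellet_events: int
    slip_events: int
    success_events: int
    reach_events: int

    def __post_init__(self) -> None:
        if not 0 <= self.reaches_successful <= self.reaches_all:
            raise ValueError(
                "reaches_successful must lie in [0, reaches_all]"
            )

    @property
    def k_success(self) -> float:
        return success_coefficient(self)


def success_coefficient(counts: OutcomeCounts) -> float:
    """k_success = reaches_successful² / reaches_all.

    Undefined (NaN) for a session with no reaches toward baited wells:
    zero attempts is not the same performance as failed attempts.
    """
    if counts.reaches_all == 0:
        return math.nan
    return counts.reaches_successful**2 / counts.reaches_all


def path_length(
    window: tuple[int, int],
    paw_xy: np.ndarray,
    px_per_cm: float,
) -> float:
    """Total path length Σ√(Δx²+Δy²) over a half-open frame window, cm."""
    start, end = window
    seg = paw_xy[start:end]
    if len(seg) < 2:
        return 0.0
    steps = np.hypot(np.diff(seg[:, 0]), np.diff(seg[:, 1]))
    return float(steps.sum() / px_per_cm)


def speed_profile(
    window: tuple[int, int],
    paw_xy: np.ndarray,
    fps: float,
    px_per_cm: float,
) -> np.ndarray:
    """Instantaneous speed (cm/s), one sample per frame interval."""
    start, end = window
    seg = paw_xy[start:end]
    steps = np.hypot(np.diff(seg[:, 0]), np.diff(seg[:, 1]))
    return steps * fps / px_per_cm


def acceleration_profile(
    window: tuple[int, int],
    paw_xy: np.ndarray,
    fps: float,
    px_per_cm: float,
) -> np.ndarray:
    """Signed acceleration a = Δv/Δt (cm/s²); empty for short windows."""
    v = speed_profile(window, paw_xy, fps, px_per_cm)
    if len(v) < 2:
        return np.empty(0)
    return np.diff(v) * fps


def _scope_features(
    window: tuple[int, int],
    v: np.ndarray,
    a_samples: np.ndarray,
    paw_xy: np.ndarray,
    fps: float,
    px_per_cm: float,
) -> dict[str, float]:
    start, end = window
    n_intervals = max(end - start - 1, 0)
    duration = n_intervals / fps
    dist = path_length(window, paw_xy, px_per_cm)
    out = {
        "distance_cm": dist,
        "duration_s": duration,
        "velocity_mean": dist / duration if duration > 0 else math.nan,
        "acceleration_mean": float(np.mean(a_samples)) if len(a_samples) else math.nan,
        "velocity_min": float(np.min(v)) if len(v) else math.nan,
        "velocity_max": float(np.max(v)) if len(v) else math.nan,
        "acceleration_min": float(np.min(a_samples)) if len(a_samples) else math.nan,
        "acceleration_max": float(np.max(a_samples)) if len(a_samples) else math.nan,
    }
    return out


def event_kinematics(
    event: MotionEvent,
    traj: CleanTrajectory,
    layout: ChamberLayout,
) -> KinematicFeatures:
    """Kinematic summaries of one segmented reaching attempt.

    Velocity samples live on frame intervals [f, f+1]; an interval
    belongs to the reach phase when f < inversion, else to the
    retraction phase, so phase durations and distances are exactly
    additive to the full attempt.
    """
    if event.kind != "reach" or event.inversion is None:
        raise ValueError("event_kinematics requires a segmented reach")
    usable = traj.usable_mask(layout.paw_landmark)
    if not usable[event.start : event.end].all():
        raise ValueError(
            "event window contains unusable frames; exclude from kinematics"
        )
    paw = traj.xy(layout.paw_landmark)
    fps, scale = layout.fps, layout.px_per_cm
    full = (event.start, event.end)
    v = speed_profile(full, paw, fps, scale)  # sample i -> interval start+i
    a = acceleration_profile(full, paw, fps, scale)
    inv = event.inversion
    per_scope = {}
    for scope, (w0, w1) in {
        "attempt": full,
        "reach": (event.start, inv),
        "retraction": (inv, event.end),
    }.items():
        # interval f in scope iff w0 <= f < w1 (attempt: < end-1)
        i0, i1 = w0 - event.start, min(w1, event.end - 1) - event.start
        a0, a1 = i0, max(i0, min(i1, len(a)))
        per_scope[scope] = _scope_features(
            (w0, min(w1 + 1, event.end)), v[i0:i1], a[a0:a1], paw, fps, scale
        )
    # phase windows overlap at the inversion frame for distance purposes:
    # reach covers intervals [start, inv), retraction [inv, end-1)
    return KinematicFeatures(per_scope=per_scope)


def slip_depth(
    event: MotionEvent,
    traj: CleanTrajectory,
    layout: ChamberLayout,
) -> float:
    """Slip depth: deepest vertical excursion below the platform, cm.

    Image convention, so "below" means y larger than ``platform_y``.
    Floored at zero (a paw that never crosses the platform edge has
    zero depth); a warning flags that degenerate case.
    """
    import warnings

    if event.kind != "slip":
        raise ValueError("slip_depth requires a slip event")
    paw = traj.xy(layout.paw_landmark)
    y_max = float(np.max(paw[event.start : event.end, 1]))
    depth_px = y_max - layout.platform_y
    if depth_px <= 0:
        warnings.warn(
            f"slip at frame {event.start} never crossed the platform edge",
            stacklevel=2,
        )
        return 0.0
    return depth_px / layout.px_per_cm


def session_features(
    events: list[MotionEvent],
    outcomes: list[ReachOutcome],
    signals: list[PelletSignal],
    traj: CleanTrajectory,
    layout: ChamberLayout,
    *,
    animal: str = "NA",
    session: str = "NA",
    day: str = "NA",
) -> dict[str, float | str]:
    """Assemble the 30-parameter feature row for one body side.

    Kinematic summaries are arithmetic means over the session's
    segmented reaches (events with unusable frames inside their window
    are skipped with a warning); counts come from the outcome
    classification; slip depth is the session mean over slips. A
    session without reaches leaves kinematics as NaN — missing, not
    zero.
    """
    import warnings

    reaches = [e for e in events if e.kind == "reach"]
    slips = [e for e in events if e.kind == "slip"]
    success = [o for o in outcomes if o.outcome == "success"]
    counts = OutcomeCounts(
        reaches_all=sum(1 for r in reaches if not r.target_emptied),
        reaches_successful=sum(
            1 for o in success if not o.event.target_emptied
        ),
        pellet_events=sum(1 for s in signals if s.removed),
        slip_events=len(slips),
        success_events=len(success),
        reach_events=len(reaches),
    )

    row: dict[str, float | str] = {
        "animal": animal,
        "session": session,
        "day": day,
        "side": layout.side,
        "k_success": counts.k_success,
        "success_events": counts.success_events,
        "pellet_events": counts.pellet_events,
        "reach_events": counts.reach_events,
        "slip_events": counts.slip_events,
    }

    kin_rows = []
    for ev in reaches:
        try:
            kin_rows.append(event_kinematics(ev, traj, layout).flat())
        except ValueError:
            warnings.warn(
                f"reach at frame {ev.start} excluded from kinematics "
                "(unusable frames in window)",
                stacklevel=2,
            )
    for scope in SCOPES:
        for fieldname in KIN_FIELDS:
            key = f"{scope}_{fieldname}"
            vals = [k[key] for k in kin_rows if not math.isnan(k[key])]
            row[key] = float(np.mean(vals)) if vals else math.nan

    depths = [slip_depth(ev, traj, layout) for ev in slips]
    row["slip_depth_cm"] = float(np.mean(depths)) if depths else math.nan
    return row


def features_frame(rows: list[dict]) -> pd.DataFrame:
    """Feature rows as a DataFrame with the documented column order."""
    return pd.DataFrame(rows, columns=list(ID_COLUMNS) + FEATURE_COLUMNS)


def normalized_to_baseline(
    features: pd.DataFrame,
    column: str,
    baseline_day: str | int,
) -> pd.Series:
    """Post-hoc utility: divide a feature by each animal's (same-side)
    baseline-day mean, e.g. reach duration relative to pre-lesion."""
    base = (
        features[features["day"] == baseline_day]
        .groupby(["animal", "side"])[column]
        .mean()
    )
    keys = list(zip(features["animal"], features["side"]))
    denom = np.array([base.get(k, np.nan) for k in keys])
    return features[column] / denom
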