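"""Pellet presence, removal detection, drop detection, reach outcomes.

Each staircase well carries one sugar pellet whose tracking likelihood
acts as a frame-by-frame pellet-existence probability. A removal
candidate opens when the probability falls below the presence
threshold (default 99 %) and stays there for at least the debounce
interval — brief dips are paw occlusions during a reach, not removals.
A provisional removal is confirmed only if the likelihood does not
recover *at the well* (within the well radius) before the next
reaching attempt; recovery at the well means the pellet was merely
occluded.

Confirmed removals are matched in time to reaching attempts, and the
joint pellet/paw trajectory after removal decides the outcome: if the
pellet simply disappears before the next reach it was eaten (success);
if the pellet landmark is re-acquired clear of every well and below its
source well — or seen separating from the paw while falling — the
pellet was dropped and the reach is unsuccessful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig, ChamberLayout
from .events import MotionEvent
from .preprocess import CleanTrajectory

__all__ = [
    "PelletSignal",
    "ReachOutcome",
    "pellet_presence_signal",
    "match_removal_to_reach",
    "detect_drop",
    "classify_reach_outcome",
    "analyze_pellets",
]


@dataclass
class PelletSignal:
    """Presence signal for one well's pellet.

    ``present`` is the debounced binary presence series; after a
    confirmed removal it is False for good (monotone non-increasing).
    ``removal_frame`` is the first frame of the confirmed
    below-threshold run, or None if the pellet never left the well.
    """

    well: int
    probability: np.ndarray
    present: np.ndarray
    removal_frame: int | None
    spontaneous: bool = False  # removal with no plausible reach

    @property
    def removed(self) -> bool:
        return self.removal_frame is not None


@dataclass
class ReachOutcome:
    """Outcome of one reaching attempt."""

    event: MotionEvent
    outcome: str  # "no_contact" | "success" | "drop"
    removal_frame: int | None = None
    drop_frame: int | None = None

    def __post_init__(self) -> None:
        if self.outcome not in ("no_contact", "success", "drop"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome in ("success", "drop") and self.removal_frame is None:
            raise ValueError(f"{self.outcome} outcome requires a removal frame")
        if self.outcome == "no_contact" and (
            self.removal_frame is not None or self.drop_frame is not None
        ):
            raise ValueError("no_contact outcome cannot carry removal/drop frames")
        if self.outcome == "drop" and self.drop_frame is None:
            raise ValueError("drop outcome requires a drop frame")


def _below_runs(below: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of True."""
    below = np.asarray(below, dtype=bool)
    padded = np.concatenate([[False], below, [False]]).astype(int)
    d = np.diff(padded)
    return list(zip(np.flatnonzero(d == 1).tolist(), np.flatnonzero(d == -1).tolist()))


def pellet_presence_signal(
    probability: np.ndarray,
    well: int,
    threshold: float = 0.99,
    debounce: int = 5,
    *,
    recovery_ok: np.ndarray | None = None,
) -> PelletSignal:
    """Debounced presence signal and provisional removal for one well.

    A below-threshold run shorter than ``debounce`` frames never
    toggles presence (occlusion dip). The first run of at least
    ``debounce`` frames opens a provisional removal at its first frame.
    Confirmation against later recovery *at the well* is handled by
    ``recovery_ok``: a boolean per-frame series that is True where a
    high likelihood should count as the pellet being back in its well
    (i.e. the landmark sits within the well radius). When the
    likelihood recovers on a ``recovery_ok`` frame before the caller's
    confirmation horizon, the provisional removal is cancelled and the
    scan continues with the next run.

    This function performs debouncing and run bookkeeping only; the
    reach-aware confirmation horizon is applied in
    :func:`analyze_pellets`, which knows the reach schedule.
    """
    prob = np.asarray(probability, dtype=float)
    below = prob < threshold
    present = ~below
    removal: int | None = None
    for start, end in _below_runs(below):
        if end - start < debounce:
            # occlusion dip: keep presence on
            present[start:end] = True
            continue
        removal = start
        break
    if removal is not None:
        present[removal:] = False
        present[:removal] = True
    else:
        present[:] = True
    return PelletSignal(
        well=well, probability=prob, present=present, removal_frame=removal
    )


def _confirmed_removal(
    prob: np.ndarray,
    in_well: np.ndarray,
    threshold: float,
    debounce: int,
    reach_starts: np.ndarray,
) -> int | None:
    """First below-threshold run that (a) lasts >= debounce frames and
    (b) shows no in-well likelihood recovery before the next reaching
    attempt after the run opens. Returns its first frame, or None."""
    n = len(prob)
    below = prob < threshold
    for start, end in _below_runs(below):
        if end - start < debounce:
            continue
        later = reach_starts[reach_starts > start]
        horizon = int(later[0]) if len(later) else n
        # recovery at the well between run end and the horizon => occlusion
        lo, hi = end, max(end, horizon)
        if hi > lo and np.any((prob[lo:hi] >= threshold) & in_well[lo:hi]):
            continue
        return start
    return None


def match_removal_to_reach(
    removal_frame: int,
    well: int,
    reaches: list[MotionEvent],
) -> MotionEvent | None:
    """Match a confirmed removal to its reaching attempt.

    Preference order: the reach whose window contains the removal
    frame; otherwise the nearest preceding reach that targeted the
    same well. A removal with neither is spontaneous (the pellet left
    its well without a plausible reach) and counts as a pellet event
    but not a success.
    """
    containing = [
        r for r in reaches if r.start <= removal_frame < r.end
    ]
    if containing:
        return containing[-1]
    preceding = [
        r
        for r in reaches
        if r.end <= removal_frame and r.target_well == well
    ]
    if preceding:
        return max(preceding, key=lambda r: r.end)
    return None


def detect_drop(
    pellet_prob: np.ndarray,
    pellet_xy: np.ndarray,
    paw_xy: np.ndarray,
    source_well_xy: tuple[float, float],
    layout: ChamberLayout,
    removal_frame: int,
    next_reach_start: int,
    config: AnalysisConfig,
) -> int | None:
    """Detect a pellet drop in the window [removal, next reach).

    A drop is declared at the first frame where the pellet landmark is
    re-acquired (likelihood back above threshold) and either

    * sits clear of every well's radius with net downward displacement
      relative to its source well (it fell past the staircase), or
    * is moving downward while separated from the paw by more than
      ``divergence_px`` (it parted company with the paw mid-carry).

    A pellet co-moving with the paw (small separation) is being
    carried, and a pellet that never reappears before the next reach
    was eaten; neither is a drop.
    """
    n = len(pellet_prob)
    lo = int(removal_frame)
    hi = int(min(max(next_reach_start, lo), n))
    if hi <= lo:
        return None
    centers = np.asarray(layout.well_centers)
    wx, wy = source_well_xy
    seen = pellet_prob[lo:hi] >= config.pellet_prob_threshold
    frames = np.flatnonzero(seen) + lo
    for f in frames:
        px, py = pellet_xy[f]
        if not (np.isfinite(px) and np.isfinite(py)):
            continue
        d_wells = np.hypot(centers[:, 0] - px, centers[:, 1] - py)
        clear_of_wells = bool(np.all(d_wells > config.well_radius_px))
        fell_below = py > wy + config.well_radius_px
        if clear_of_wells and fell_below:
            return int(f)
        if f + 1 < hi:
            moving_down = pellet_xy[f + 1, 1] > py
            apart = (
                np.hypot(paw_xy[f, 0] - px, paw_xy[f, 1] - py)
                > config.divergence_px
            )
            if moving_down and apart and clear_of_wells:
                return int(f)
    return None


def classify_reach_outcome(
    reach: MotionEvent,
    removal_frame: int | None,
    drop_frame: int | None,
) -> ReachOutcome:
    """Combine matching and drop detection into the reach outcome."""
    if removal_frame is None:
        return ReachOutcome(event=reach, outcome="no_contact")
    if drop_frame is None:
        return ReachOutcome(
            event=reach, outcome="success", removal_frame=removal_frame
        )
    return ReachOutcome(
        event=reach,
        outcome="drop",
        removal_frame=removal_frame,
        drop_frame=drop_frame,
    )


def analyze_pellets(
    traj: CleanTrajectory,
    events: list[MotionEvent],
    layout: ChamberLayout,
    config: AnalysisConfig | None = None,
) -> tuple[list[PelletSignal], list[ReachOutcome]]:
    """Pellet analysis for one body side.

    Builds per-well presence signals with reach-aware removal
    confirmation, assigns reach targets in chronological order (so the
    already-emptied bookkeeping reflects removal order), matches
    removals to reaches, runs drop detection and classifies every
    reach. Mutates the events' ``target_well``/``target_emptied``.
    """
    from .events import assign_target_well

    config = config or AnalysisConfig()
    reaches = sorted(
        (e for e in events if e.kind == "reach"), key=lambda e: e.start
    )
    reach_starts = np.array([r.start for r in reaches], dtype=int)
    paw_xy = traj.xy(layout.paw_landmark)
    n = traj.n_frames

    # per-well signals with reach-aware confirmation
    signals: list[PelletSignal] = []
    for w, name in enumerate(layout.well_names, start=1):
        j = traj.table.index(name)
        prob = np.nan_to_num(traj.table.likelihood[:, j], nan=0.0)
        cx, cy = layout.well_centers[w - 1]
        px = traj.table.x[:, j]
        py = traj.table.y[:, j]
        with np.errstate(invalid="ignore"):
            in_well = (
                np.isfinite(px)
                & np.isfinite(py)
                & (np.hypot(px - cx, py - cy) <= config.well_radius_px)
            )
        removal = _confirmed_removal(
            prob,
            in_well,
            config.pellet_prob_threshold,
            config.removal_debounce,
            reach_starts,
        )
        sig = pellet_presence_signal(
            prob, w, config.pellet_prob_threshold, config.removal_debounce
        )
        sig.removal_frame = removal
        sig.present = np.ones(n, dtype=bool)
        if removal is not None:
            sig.present[removal:] = False
        signals.append(sig)

    # chronological target assignment with emptied-well bookkeeping
    removal_by_well = {
        s.well: s.removal_frame for s in signals if s.removal_frame is not None
    }
    for r in reaches:
        emptied_now = {
            w for w, f in removal_by_well.items() if f < r.start
        }
        inv_xy = paw_xy[r.inversion]
        well, emptied = assign_target_well(inv_xy, layout, emptied_now)
        r.target_well = well
        r.target_emptied = emptied

    # match removals to reaches; drop detection; outcomes
    matched: dict[int, tuple[int, int]] = {}  # id(reach) -> (well, removal)
    for sig in signals:
        if sig.removal_frame is None:
            continue
        reach = match_removal_to_reach(sig.removal_frame, sig.well, reaches)
        if reach is None:
            sig.spontaneous = True
            continue
        matched[id(reach)] = (sig.well, sig.removal_frame)

    outcomes: list[ReachOutcome] = []
    for i, r in enumerate(reaches):
        if id(r) not in matched:
            outcomes.append(classify_reach_outcome(r, None, None))
            continue
        well, removal = matched[id(r)]
        nxt = next((q.start for q in reaches[i + 1 :]), n)
        j = traj.table.index(layout.well_names[well - 1])
        pellet_xy = np.column_stack(
            [traj.table.x[:, j], traj.table.y[:, j]]
        )
        drop = detect_drop(
            np.nan_to_num(traj.table.likelihood[:, j], nan=0.0),
            pellet_xy,
            paw_xy,
            layout.well_centers[well - 1],
            layout,
            removal,
            nxt,
            config,
        )
        outcomes.append(classify_reach_outcome(r, removal, drop))
    return signals, outcomes
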