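"""End-to-end session processing and the run manifest.

``run_session`` takes a raw trajectory table plus chamber config and
drives the full pipeline per configured side — cleaning, event
detection, pellet analysis, outcome classification, kinematics — and
returns tidy events and features tables plus a :class:`RunManifest`
with per-stage counts and collected warnings, for reproducibility
audits.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ChamberConfig
from .events import MotionEvent, detect_events
from .io import TrajectoryTable
from .kinematics import features_frame, session_features
from .pellets import PelletSignal, ReachOutcome, analyze_pellets
from .preprocess import CleanTrajectory, preprocess

__all__ = ["RunManifest", "SessionResult", "run_session", "events_frame"]


def _package_version() -> str:
    try:
        return version("stairreach")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunManifest:
    """Provenance and per-stage counts for one pipeline run."""

    config_hash: str
    software_version: str = field(default_factory=_package_version)
    inputs: list[str] = field(default_factory=list)
    n_frames: int = 0
    frames_jump_rejected: int = 0
    frames_gap_filled: int = 0
    events_by_kind: dict[str, int] = field(default_factory=dict)
    removals: int = 0
    spontaneous_removals: int = 0
    outcomes: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def check_consistency(self) -> None:
        n_reach = self.events_by_kind.get("reach", 0)
        if sum(self.outcomes.values()) != n_reach:
            raise ValueError("outcome counts do not sum to reach events")

    def to_dict(self) -> dict:
        return {
            "software_version": self.software_version,
            "config_hash": self.config_hash,
            "inputs": self.inputs,
            "n_frames": self.n_frames,
            "frames_jump_rejected": self.frames_jump_rejected,
            "frames_gap_filled": self.frames_gap_filled,
            "events_by_kind": self.events_by_kind,
            "removals": self.removals,
            "spontaneous_removals": self.spontaneous_removals,
            "outcomes": self.outcomes,
            "warnings": self.warnings,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class SessionResult:
    """Everything one session run produces."""

    clean: CleanTrajectory
    events: dict[str, list[MotionEvent]]
    signals: dict[str, list[PelletSignal]]
    outcomes: dict[str, list[ReachOutcome]]
    events_df: pd.DataFrame
    features_df: pd.DataFrame
    manifest: RunManifest


def events_frame(
    events: dict[str, list[MotionEvent]],
    outcomes: dict[str, list[ReachOutcome]],
) -> pd.DataFrame:
    """Flatten per-side events + outcomes into the events table."""
    outcome_by_event: dict[int, ReachOutcome] = {}
    for side_outcomes in outcomes.values():
        for o in side_outcomes:
            outcome_by_event[id(o.event)] = o
    rows = []
    for side, evs in events.items():
        for e in evs:
            o = outcome_by_event.get(id(e))
            rows.append(
                {
                    "side": side,
                    "kind": e.kind,
                    "start": e.start,
                    "inversion": e.inversion if e.inversion is not None else -1,
                    "end": e.end,
                    "displacement_ratio": e.displacement_ratio,
                    "peak_speed": e.peak_speed,
                    "target_well": e.target_well or -1,
                    "target_emptied": int(e.target_emptied),
                    "outcome": o.outcome if o else "n/a",
                    "removal_frame": (
                        o.removal_frame
                        if o and o.removal_frame is not None
                        else -1
                    ),
                    "drop_frame": (
                        o.drop_frame if o and o.drop_frame is not None else -1
                    ),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "side",
            "kind",
            "start",
            "inversion",
            "end",
            "displacement_ratio",
            "peak_speed",
            "target_well",
            "target_emptied",
            "outcome",
            "removal_frame",
            "drop_frame",
        ],
    )
    return df.sort_values(["start", "side"], kind="stable").reset_index(
        drop=True
    )


def run_session(
    table: TrajectoryTable,
    chamber: ChamberConfig,
    *,
    animal: str = "NA",
    session: str = "NA",
    day: str = "NA",
    inputs: list[str] | None = None,
) -> SessionResult:
    """Run the full pipeline on one session's trajectory table."""
    manifest = RunManifest(
        config_hash=chamber.config_hash(), inputs=inputs or []
    )
    manifest.n_frames = table.n_frames

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        clean = preprocess(table, chamber.analysis)
        events: dict[str, list[MotionEvent]] = {}
        signals: dict[str, list[PelletSignal]] = {}
        outcomes: dict[str, list[ReachOutcome]] = {}
        feature_rows = []
        for side in chamber.sides:
            layout = chamber.layout(side)
            evs = detect_events(clean, layout, chamber.analysis)
            sigs, outs = analyze_pellets(clean, evs, layout, chamber.analysis)
            events[side] = evs
            signals[side] = sigs
            outcomes[side] = outs
            feature_rows.append(
                session_features(
                    evs,
                    outs,
                    sigs,
                    clean,
                    layout,
                    animal=animal,
                    session=session,
                    day=day,
                )
            )
    manifest.warnings = sorted({str(w.message) for w in caught})

    paw_cols = [
        clean.table.index(chamber.layout(s).paw_landmark)
        for s in chamber.sides
    ]
    manifest.frames_jump_rejected = int(
        clean.jump_rejected[:, paw_cols].sum()
    )
    manifest.frames_gap_filled = int(clean.gap_filled[:, paw_cols].sum())
    all_events = [e for evs in events.values() for e in evs]
    manifest.events_by_kind = {
        k: sum(1 for e in all_events if e.kind == k)
        for k in ("reach", "slip")
    }
    all_signals = [s for sigs in signals.values() for s in sigs]
    manifest.removals = sum(1 for s in all_signals if s.removed)
    manifest.spontaneous_removals = sum(
        1 for s in all_signals if s.spontaneous
    )
    all_outcomes = [o for outs in outcomes.values() for o in outs]
    manifest.outcomes = {
        k: sum(1 for o in all_outcomes if o.outcome == k)
        for k in ("no_contact", "success", "drop")
    }
    manifest.check_consistency()

    return SessionResult(
        clean=clean,
        events=events,
        signals=signals,
        outcomes=outcomes,
        events_df=events_frame(events, outcomes),
        features_df=features_frame(feature_rows),
        manifest=manifest,
    )


def removals_frame(signals: dict[str, list[PelletSignal]]) -> pd.DataFrame:
    """Confirmed removals as a tidy table (side, well, removal_frame)."""
    rows = [
        {
            "side": side,
            "well": s.well,
            "removal_frame": s.removal_frame,
            "spontaneous": s.spontaneous,
        }
        for side, sigs in signals.items()
        for s in sigs
        if s.removed
    ]
    return pd.DataFrame(
        rows, columns=["side", "well", "removal_frame", "spontaneous"]
    )
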