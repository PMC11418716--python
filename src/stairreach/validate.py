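"""Validation of detected events against a ground-truth event log.

Detections and truth are matched one-to-one per event kind (and side)
by greedy nearest-start-frame pairing within a frame tolerance, the
same protocol used to score automated detections against manual
annotation. Sensitivity is matched truth over all truth, precision is
matched detections over all detections, and a binwise accuracy over
1-second bins reports how often detection and truth agree about
whether an event (of the kind) was ongoing in each bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KindReport", "ValidationReport", "match_events", "validate_events",
           "validate_removals"]


@dataclass
class KindReport:
    """Match statistics for one event kind."""

    kind: str
    n_truth: int
    n_detected: int
    n_matched: int
    bin_accuracy: float = float("nan")

    @property
    def sensitivity(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return (
            self.n_matched / self.n_detected if self.n_detected else float("nan")
        )

    def to_dict(self) -> dict:
        def _num(v: float):
            return None if v != v else v  # NaN -> null in JSON

        return {
            "kind": self.kind,
            "n_truth": self.n_truth,
            "n_detected": self.n_detected,
            "n_matched": self.n_matched,
            "sensitivity": _num(self.sensitivity),
            "precision": _num(self.precision),
            "bin_accuracy": _num(self.bin_accuracy),
        }


@dataclass
class ValidationReport:
    per_kind: dict[str, KindReport] = field(default_factory=dict)
    tolerance: int = 10

    def to_dict(self) -> dict:
        return {
            "tolerance_frames": self.tolerance,
            "kinds": {k: r.to_dict() for k, r in self.per_kind.items()},
        }


def match_events(
    detected_starts: np.ndarray,
    truth_starts: np.ndarray,
    tolerance: int,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching by nearest start frame.

    Candidate pairs within ``tolerance`` frames are taken in order of
    increasing start-frame distance; each detection and each truth
    event is used at most once. Returns (detected_idx, truth_idx)
    pairs. Swapping the two lists swaps sensitivity and precision but
    produces the same matching.
    """
    pairs = [
        (abs(int(d) - int(t)), i, j)
        for i, d in enumerate(detected_starts)
        for j, t in enumerate(truth_starts)
        if abs(int(d) - int(t)) <= tolerance
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matches.append((i, j))
    return matches


def _bin_accuracy(
    detected: pd.DataFrame, truth: pd.DataFrame, n_frames: int, fps: float
) -> float:
    """Fraction of 1-s bins where detection and truth agree on event
    presence."""
    n_bins = max(int(np.ceil(n_frames / fps)), 1)

    def occupancy(df: pd.DataFrame) -> np.ndarray:
        occ = np.zeros(n_bins, dtype=bool)
        for _, row in df.iterrows():
            b0 = int(row["start"] // fps)
            b1 = int((row["end"] - 1) // fps)
            occ[b0 : b1 + 1] = True
        return occ

    return float(np.mean(occupancy(detected) == occupancy(truth)))


def validate_events(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    tolerance: int = 10,
    *,
    n_frames: int | None = None,
    fps: float = 100.0,
) -> ValidationReport:
    """Validate a detected events table against a ground-truth log.

    Both tables need ``side``, ``kind``, ``start`` (and ``end`` for
    bin accuracy) columns; matching is done separately per (side,
    kind) so a reach can never satisfy a slip annotation.
    """
    report = ValidationReport(tolerance=tolerance)
    kinds = sorted((set(truth["kind"]) | set(detected["kind"])) - {"n/a"})
    if n_frames is None:
        tops = [df["end"].max() for df in (detected, truth) if len(df)]
        n_frames = int(max(tops)) if tops else 1
    for kind in kinds:
        n_truth = n_det = n_matched = 0
        for side in ("left", "right"):
            t = truth[(truth["kind"] == kind) & (truth["side"] == side)]
            d = detected[
                (detected["kind"] == kind) & (detected["side"] == side)
            ]
            n_truth += len(t)
            n_det += len(d)
            n_matched += len(
                match_events(
                    d["start"].to_numpy(),
                    t["start"].to_numpy(),
                    tolerance,
                )
            )
        rep = KindReport(kind, n_truth, n_det, n_matched)
        rep.bin_accuracy = _bin_accuracy(
            detected[detected["kind"] == kind],
            truth[truth["kind"] == kind],
            n_frames,
            fps,
        )
        report.per_kind[kind] = rep
    return report


def validate_removals(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    tolerance: int = 10,
) -> KindReport:
    """Validate confirmed pellet removals per well against ground truth.

    ``detected`` needs side/well/removal_frame rows; ``truth`` is the
    generator event log (reaches with ``removal_frame >= 0``). Matching
    is exact per (side, well) with the removal frame within tolerance.
    """
    t = truth[(truth["kind"] == "reach") & (truth["removal_frame"] >= 0)]
    n_truth = len(t)
    n_det = len(detected)
    n_matched = 0
    for side in ("left", "right"):
        for well in range(1, 9):
            td = t[(t["side"] == side) & (t["target_well"] == well)]
            dd = detected[
                (detected["side"] == side) & (detected["well"] == well)
            ]
            n_matched += len(
                match_events(
                    dd["removal_frame"].to_numpy(),
                    td["removal_frame"].to_numpy(),
                    tolerance,
                )
            )
    return KindReport("removal", n_truth, n_det, n_matched)
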