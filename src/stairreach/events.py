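"""Paw event detection: velocity thresholding, reach/slip classification,
phase segmentation and target-well assignment.

A reaching attempt is an out-and-back excursion of the forepaw from its
rest posture on the stabilizing platform toward a staircase well; a
slip is a sudden, predominantly vertical drop of the paw off the
platform edge. Both produce the same velocity signature — movement away
from rest, a turning point, movement back — so both are detected from a
*signed outward velocity* signal: the frame derivative of the paw's
distance from its rest position (positive while moving away, negative
while returning). A candidate event is a local maximum of that signal
followed by a local minimum, both at least ``velocity_threshold``
(default 1.5 px/frame) in magnitude; the event window is then extended
outward to the enclosing zero crossings, and overlapping candidates are
merged.

Classification uses the ratio of mean horizontal to mean vertical
frame-to-frame displacement over the window: a ratio below
``slip_ratio_threshold`` (default 1.5) identifies a slip, anything
else a reach. Slips are only scored when the paw starts within a band
around the platform edge; reach phases are split at the inversion
point (the turning point of the excursion), and the reach target is
the staircase well nearest the paw at inversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import AnalysisConfig, ChamberLayout
from .preprocess import CleanTrajectory, usable_spans

__all__ = [
    "VelocitySeries",
    "MotionEvent",
    "compute_velocity",
    "rest_position",
    "outward_velocity",
    "detect_event_candidates",
    "classify_event",
    "segment_reach_phases",
    "assign_target_well",
    "detect_events",
]


@dataclass
class VelocitySeries:
    """Frame-to-frame velocity of one landmark.

    ``vx[f]`` is ``x[f+1] - x[f]`` (px/frame); ``speed`` its Euclidean
    norm; a sample is valid only when both frames of the difference are
    usable, so velocities never straddle a span boundary.
    """

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.vx)


@dataclass
class MotionEvent:
    """A detected paw event with half-open frame window [start, end)."""

    side: str
    kind: str  # "reach" | "slip"
    start: int
    end: int
    inversion: int | None  # turning-point frame (reach only)
    displacement_ratio: float
    peak_speed: float
    target_well: int | None = None  # 1..8
    target_emptied: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("reach", "slip"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError("event window must satisfy start < end")
        if self.kind == "reach" and self.inversion is not None:
            if not self.start < self.inversion < self.end:
                raise ValueError("inversion must lie strictly inside window")

    @property
    def duration_frames(self) -> int:
        return self.end - self.start


def compute_velocity(
    traj: CleanTrajectory, landmark: str
) -> VelocitySeries:
    """Frame-difference velocity series for one landmark."""
    p = traj.xy(landmark)
    usable = traj.usable_mask(landmark)
    vx = np.diff(p[:, 0])
    vy = np.diff(p[:, 1])
    valid = usable[:-1] & usable[1:]
    vx = np.where(valid, vx, 0.0)
    vy = np.where(valid, vy, 0.0)
    return VelocitySeries(vx=vx, vy=vy, speed=np.hypot(vx, vy), valid=valid)


def rest_position(traj: CleanTrajectory, landmark: str) -> np.ndarray:
    """Rest posture of a paw: per-axis median over usable frames.

    The paw spends the majority of a session at rest on the platform,
    so the coordinate-wise median is a robust estimate of the rest
    posture that individual reaches cannot drag around.
    """
    p = traj.xy(landmark)
    m = traj.usable_mask(landmark)
    if not m.any():
        raise ValueError(f"no usable frames for {landmark}")
    return np.array([np.median(p[m, 0]), np.median(p[m, 1])])


def outward_velocity(
    traj: CleanTrajectory, landmark: str, rest: np.ndarray | None = None
) -> np.ndarray:
    """Signed outward-velocity signal (px/frame), one sample per frame
    pair: the frame difference of the paw's Euclidean distance from its
    rest position. Positive while the paw moves away from rest (toward
    a well, or down off the platform), negative while it returns. Zero
    on samples spanning unusable frames.
    """
    if rest is None:
        rest = rest_position(traj, landmark)
    p = traj.xy(landmark)
    r = np.hypot(p[:, 0] - rest[0], p[:, 1] - rest[1])
    usable = traj.usable_mask(landmark)
    v = np.diff(r)
    valid = usable[:-1] & usable[1:]
    return np.where(valid, v, 0.0)


def _local_maxima(v: np.ndarray) -> np.ndarray:
    """Indices f with v[f-1] < v[f] >= v[f+1] (left-biased plateaus)."""
    if len(v) < 3:
        return np.array([], dtype=int)
    left = v[1:-1] > v[:-2]
    right = v[1:-1] >= v[2:]
    return np.flatnonzero(left & right) + 1


def detect_event_candidates(
    v_out: np.ndarray,
    threshold: float = 1.5,
    min_frames: int = 3,
    spans: Sequence[tuple[int, int]] | None = None,
    zero_band: float = 0.0,
) -> list[tuple[int, int, int]]:
    """Detect candidate event windows from the signed outward velocity.

    Within each usable span, every local maximum of ``v_out`` at or
    above ``threshold`` is paired with the next local minimum at or
    below ``-threshold`` (movement away, then back). The window is
    extended to the enclosing zero crossings: the start of the positive
    run containing the maximum, and the end of the negative run
    containing the minimum. ``zero_band`` is the numerical zero used
    for that extension — on real (noisy) signals the velocity hovers
    around zero at rest, and treating |v| below a small band as zero
    anchors event boundaries at movement onset instead of letting them
    wander into the rest noise. Overlapping or abutting windows are
    merged. Windows shorter than ``min_frames`` frames are dropped as
    flicker.

    Returns ``(start, end, peak_sample)`` triples with half-open frame
    windows; ``peak_sample`` is the velocity-sample index of the
    (largest) outward maximum, kept for inversion refinement.
    """
    if threshold <= 0:
        raise ValueError("velocity threshold must be > 0")
    if not 0 <= zero_band < threshold:
        raise ValueError("zero_band must be in [0, threshold)")
    n = len(v_out)
    if spans is None:
        spans = [(0, n + 1)] if n else []
    windows: list[tuple[int, int, int]] = []
    for s0, s1 in spans:
        a, b = s0, min(s1 - 1, n)  # velocity-sample range [a, b)
        if b - a < 2:
            continue
        seg = v_out[a:b]
        maxima = [a + f for f in _local_maxima(seg) if v_out[a + f] >= threshold]
        minima = [a + f for f in _local_maxima(-seg) if v_out[a + f] <= -threshold]
        for m in maxima:
            # the successive pair: first qualifying minimum after this
            # maximum; several ripple maxima of one excursion pair with
            # the same minimum and their windows merge below
            mi = int(np.searchsorted(minima, m, side="right"))
            if mi == len(minima):
                continue
            nmin = minima[mi]
            # extend to enclosing zero crossings within the span
            w0 = m
            while w0 > a and v_out[w0 - 1] > zero_band:
                w0 -= 1
            w1 = nmin
            while w1 < b - 1 and v_out[w1 + 1] < -zero_band:
                w1 += 1
            # frame window: sample f spans frames [f, f+1]
            windows.append((w0, w1 + 2, m))
            mi += 1
    windows.sort()
    merged: list[tuple[int, int, int]] = []
    for w0, w1, m in windows:
        if merged and w0 <= merged[-1][1]:
            p0, p1, pm = merged[-1]
            best = pm if abs(v_out[pm]) >= abs(v_out[m]) else m
            merged[-1] = (p0, max(p1, w1), best)
        else:
            merged.append((w0, w1, m))
    return [(w0, w1, m) for w0, w1, m in merged if w1 - w0 >= min_frames]


def classify_event(
    window: tuple[int, int],
    vel: VelocitySeries,
    slip_ratio_threshold: float = 1.5,
) -> tuple[str, float]:
    """Classify a candidate window as reach or slip.

    The discriminant is the ratio of mean absolute horizontal to mean
    absolute vertical frame-to-frame displacement over the window;
    slips are dominated by vertical motion (ratio < threshold). A
    purely horizontal window (zero vertical displacement) has infinite
    ratio and is a reach. Pellet information plays no role here.
    """
    start, end = window
    sl = slice(start, max(start + 1, end - 1))
    dx = float(np.mean(np.abs(vel.vx[sl])))
    dy = float(np.mean(np.abs(vel.vy[sl])))
    ratio = np.inf if dy == 0.0 else dx / dy
    kind = "slip" if ratio < slip_ratio_threshold else "reach"
    return kind, ratio


def segment_reach_phases(
    window: tuple[int, int],
    traj: CleanTrajectory,
    landmark: str,
    rest: np.ndarray,
) -> int | None:
    """Inversion frame of a reach: the paw's turning point.

    The inversion is where the outward velocity changes sign between
    the outward maximum and the return minimum — equivalently the frame
    of greatest distance from rest within the window, which also
    handles merged multi-peak windows (deepest turning point wins).
    Returns None when the window has no interior turning point
    (monotone drift; the caller discards such events).
    """
    start, end = window
    p = traj.xy(landmark)[start:end]
    r = np.hypot(p[:, 0] - rest[0], p[:, 1] - rest[1])
    inv = start + int(np.argmax(r))
    if inv == start or inv >= end - 1:
        return None
    return inv


def assign_target_well(
    inversion_xy: np.ndarray,
    layout: ChamberLayout,
    emptied: set[int] | None = None,
) -> tuple[int, bool]:
    """Nearest staircase well (1..8) to the paw at inversion.

    Ties break to the lowest well index. ``emptied`` reports whether
    the chosen well had already lost its pellet; reaches to emptied
    wells are excluded from the denominator of the success coefficient.
    """
    centers = np.asarray(layout.well_centers)
    d = np.hypot(centers[:, 0] - inversion_xy[0], centers[:, 1] - inversion_xy[1])
    well = int(np.argmin(d)) + 1  # argmin takes the first (lowest) index
    return well, bool(emptied and well in emptied)


def detect_events(
    traj: CleanTrajectory,
    layout: ChamberLayout,
    config: AnalysisConfig | None = None,
) -> list[MotionEvent]:
    """Full event detection for one body side.

    Runs candidate detection on the signed outward velocity of the
    side's paw, classifies each window, segments reach phases, and
    discards malformed reaches (no interior turning point) and slips
    that do not start within the platform band — a paw already below
    the platform cannot slip off it. Target wells are assigned later,
    once pellet removals are known (see :mod:`stairreach.pellets`),
    because "already emptied" depends on removal order.
    """
    import warnings

    config = config or AnalysisConfig()
    paw = layout.paw_landmark
    rest = rest_position(traj, paw)
    v_out = outward_velocity(traj, paw, rest)
    vel = compute_velocity(traj, paw)
    spans = traj.spans(paw)
    windows = detect_event_candidates(
        v_out,
        threshold=config.velocity_threshold,
        min_frames=config.min_event_frames,
        spans=spans,
        zero_band=config.zero_band_px,
    )
    p = traj.xy(paw)
    events: list[MotionEvent] = []
    for start, end, _peak in windows:
        end = min(end, traj.n_frames)
        kind, ratio = classify_event((start, end), vel, config.slip_ratio_threshold)
        peak_speed = float(np.max(vel.speed[start : max(start + 1, end - 1)]))
        if kind == "slip":
            if abs(p[start, 1] - layout.platform_y) > config.platform_band_px:
                continue  # vertical motion away from the platform edge
            events.append(
                MotionEvent(
                    side=layout.side,
                    kind="slip",
                    start=start,
                    end=end,
                    inversion=None,
                    displacement_ratio=ratio,
                    peak_speed=peak_speed,
                )
            )
        else:
            inv = segment_reach_phases((start, end), traj, paw, rest)
            if inv is None:
                warnings.warn(
                    f"discarding malformed reach at frames [{start}, {end}): "
                    "no interior turning point",
                    stacklevel=2,
                )
                continue
            events.append(
                MotionEvent(
                    side=layout.side,
                    kind="reach",
                    start=start,
                    end=end,
                    inversion=inv,
                    displacement_ratio=ratio,
                    peak_speed=peak_speed,
                )
            )
    return events
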