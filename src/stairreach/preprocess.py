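"""Trajectory cleaning: jump rejection, gap filling, smoothing.

The cleaning pipeline mirrors the processing order used for markerless
tracking output of the Staircase test:

1. frames whose paw likelihood is below a confidence floor are marked
   invalid (missing data);
2. non-physiological trajectory jumps — frame-to-frame 2D displacements
   exceeding six standard deviations of the landmark's displacement
   distribution — are rejected;
3. invalid runs up to ``max_gap_fill`` frames (typically single frames)
   are filled with the coordinate means of the two nearest valid
   frames; longer runs split the trace into independent usable spans;
4. coordinates are smoothed with a centred 10-frame moving mean.

The jump rule uses the displacement *magnitude*, not per-axis
deviations; per-axis flagging is the plausible alternative reading and
would flag a superset on axis-aligned jumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig, PAW_LANDMARKS
from .io import TrajectoryTable

__all__ = [
    "CleanTrajectory",
    "flag_jumps",
    "fill_gaps",
    "smooth",
    "preprocess",
    "usable_spans",
]


@dataclass
class CleanTrajectory:
    """A cleaned trajectory table with per-frame provenance flags.

    ``usable`` marks frames that survive cleaning (originally valid or
    gap-filled); ``jump_rejected`` and ``gap_filled`` record what
    happened to each frame of each landmark.
    """

    table: TrajectoryTable
    usable: np.ndarray
    jump_rejected: np.ndarray
    gap_filled: np.ndarray
    smoothed_landmarks: list[str] = field(default_factory=list)

    @property
    def fps(self) -> float:
        return self.table.fps

    @property
    def n_frames(self) -> int:
        return self.table.n_frames

    def xy(self, landmark: str) -> np.ndarray:
        return self.table.xy(landmark)

    def usable_mask(self, landmark: str) -> np.ndarray:
        return self.usable[:, self.table.index(landmark)]

    def spans(self, landmark: str) -> list[tuple[int, int]]:
        """Half-open [start, end) runs of usable frames for a landmark."""
        return usable_spans(self.usable_mask(landmark))


def usable_spans(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open runs of True in a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def flag_jumps(
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    k: float = 6.0,
) -> np.ndarray:
    """Flag non-physiological jump frames for one landmark.

    The displacement threshold is ``k`` times the standard deviation of
    the frame-to-frame 2D displacement magnitudes, computed once over
    the initially valid frames (single filter pass, not iterated). The
    trace is then walked forward and each frame is compared against the
    most recent accepted frame, with the allowance scaled by the frame
    gap ``g`` between them (a physiological paw can cover g x threshold
    in g frames): an isolated spike rejects exactly the spike frame,
    the trace re-anchors on the next physiological frame, and a fast
    but genuine movement is never cascade-rejected behind a single
    flagged frame.

    Returns the updated validity mask. A frozen landmark (zero
    displacement SD) has no jumps by definition and is returned as-is.
    """
    if k <= 0:
        raise ValueError("sd multiplier k must be > 0")
    valid = np.asarray(valid, dtype=bool).copy()
    if valid.sum() < 3:
        raise ValueError("trajectory unusable: fewer than 3 valid frames")
    # displacement magnitudes over consecutive initially-valid frames
    both = valid[:-1] & valid[1:]
    disp = np.hypot(np.diff(x), np.diff(y))
    sample = disp[both]
    if sample.size == 0:
        return valid
    sd = float(np.std(sample))
    if sd == 0.0:
        return valid
    threshold = k * sd
    idx = np.flatnonzero(valid)
    anchor = idx[0]
    for f in idx[1:]:
        step = float(np.hypot(x[f] - x[anchor], y[f] - y[anchor]))
        if step > threshold * (f - anchor):
            valid[f] = False
        else:
            anchor = f
    if not valid.any():
        raise ValueError("trajectory unusable: all frames rejected")
    return valid


def fill_gaps(
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    max_gap: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fill short invalid runs with the mean of the flanking frames.

    Every invalid run of length <= ``max_gap`` enclosed by valid frames
    is replaced by the coordinate means of the two nearest valid
    frames. Longer runs, and leading/trailing runs (no flanking data),
    stay invalid and split the trace into independent usable spans.

    Returns ``(x, y, usable, filled)``; valid frames are never modified.
    """
    valid = np.asarray(valid, dtype=bool)
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    usable = valid.copy()
    filled = np.zeros_like(valid)
    n = len(valid)
    for start, end in usable_spans(~valid):
        if start == 0 or end == n:
            continue  # no flanking frame on one side
        if end - start > max_gap:
            continue
        xm = 0.5 * (x[start - 1] + x[end])
        ym = 0.5 * (y[start - 1] + y[end])
        x[start:end] = xm
        y[start:end] = ym
        usable[start:end] = True
        filled[start:end] = True
    return x, y, usable, filled


def _smoothing_kernel(window: int) -> np.ndarray:
    """Centred moving-mean kernel.

    Odd windows are the plain symmetric mean. An even window ``w`` is
    symmetrized as the average of the two length-``w`` windows centred
    half a frame either side (weights 1/2, 1, ..., 1, 1/2 over w+1
    taps) so the filter has zero phase delay: a trailing or off-centre
    window would shift every event boundary by ~w/2 frames.
    """
    if window < 1:
        raise ValueError("smoothing window must be >= 1")
    if window == 1:
        return np.array([1.0])
    if window % 2 == 1:
        return np.full(window, 1.0 / window)
    k = np.ones(window + 1)
    k[0] = k[-1] = 0.5
    return k / window


def smooth(
    values: np.ndarray,
    usable: np.ndarray,
    window: int = 10,
) -> np.ndarray:
    """Centred moving mean per usable span, truncated at span edges.

    Near a span boundary the kernel is clipped to the span and
    renormalized (a shrinking window), so the output is always a convex
    combination of in-span input values and never borrows data across a
    gap that was too long to fill.
    """
    kernel = _smoothing_kernel(window)
    half = (len(kernel) - 1) // 2
    out = np.asarray(values, dtype=float).copy()
    for start, end in usable_spans(usable):
        seg = out[start:end]
        if len(seg) == 1 or len(kernel) == 1:
            continue
        num = np.convolve(seg, kernel, mode="full")[half : half + len(seg)]
        den = np.convolve(np.ones_like(seg), kernel, mode="full")[
            half : half + len(seg)
        ]
        out[start:end] = num / den
    return out


def preprocess(
    table: TrajectoryTable,
    config: AnalysisConfig | None = None,
) -> CleanTrajectory:
    """Run the full cleaning pipeline on every paw landmark.

    Pellet (well) landmarks are passed through untouched: their
    likelihood trace *is* the pellet-presence signal and gap-filling or
    smoothing it would manufacture pellet evidence.
    """
    config = config or AnalysisConfig()
    clean = table.copy()
    n, m = clean.x.shape
    usable = clean.valid.copy()
    jump_rejected = np.zeros((n, m), dtype=bool)
    gap_filled = np.zeros((n, m), dtype=bool)
    smoothed: list[str] = []

    paw_names = set(PAW_LANDMARKS.values())
    for j, lm in enumerate(clean.landmarks):
        if lm not in paw_names:
            continue
        valid0 = clean.valid[:, j] & (
            clean.likelihood[:, j] >= config.paw_likelihood_floor
        )
        if valid0.sum() < 3:
            raise ValueError(f"trajectory unusable: landmark {lm}")
        valid1 = flag_jumps(
            clean.x[:, j], clean.y[:, j], valid0, k=config.jump_sd_multiplier
        )
        jump_rejected[:, j] = valid0 & ~valid1
        xf, yf, use, filled = fill_gaps(
            clean.x[:, j], clean.y[:, j], valid1, max_gap=config.max_gap_fill
        )
        gap_filled[:, j] = filled
        xs = smooth(xf, use, window=config.smoothing_window)
        ys = smooth(yf, use, window=config.smoothing_window)
        clean.x[:, j] = xs
        clean.y[:, j] = ys
        usable[:, j] = use
        smoothed.append(lm)

    clean.valid = usable.copy()
    return CleanTrajectory(
        table=clean,
        usable=usable,
        jump_rejected=jump_rejected,
        gap_filled=gap_filled,
        smoothed_landmarks=smoothed,
    )
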