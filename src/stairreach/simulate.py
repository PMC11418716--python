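"""Synthetic Staircase sessions with exhaustive ground truth.

The generator emulates what side-view markerless tracking of a mouse in
the Staircase test produces, without any video: per-frame (x, y,
likelihood) for both forepaws and the eight pellet wells per side.

* Reaching attempts are minimum-jerk out-and-back strokes from the
  paw's rest posture on the platform to a target well, with a
  configurable out/back asymmetry so the turning point is off-centre.
* Slips are vertical step-and-return displacements below the platform
  edge.
* Pellet likelihood per well sits near 1, dips transiently while the
  paw occludes the well during a reach, and collapses permanently at a
  removal. Dropped pellets reappear on a short ballistic downward
  track; carried pellets co-move with the paw before disappearing.
* Tracking artifacts: Gaussian pixel noise everywhere, single-frame
  coordinate spikes (30-80 px) and single-frame likelihood dropouts at
  Poisson-scheduled frames.

Every injected event is recorded in a :class:`GroundTruthLog` so the
pipeline's detections can be validated against a known answer — the
desk-scale analogue of manual annotation by blinded raters.

The default session (~50 reaches and ~10 slips per side, 1 px noise)
is the condition under which detection sensitivities are quoted.
Generation is a pure function of the spec: the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ChamberConfig, default_config
from .io import TrajectoryTable

__all__ = [
    "ReachSpec",
    "SlipSpec",
    "SessionSpec",
    "GroundTruthLog",
    "default_session_spec",
    "generate_session",
    "inject_artifacts",
    "generate_cohort",
]

#: paw rest postures on the platform (px), per side
REST_POSITIONS = {"left": (155.0, 60.0), "right": (165.0, 60.0)}

_MJ_PEAK = 1.875  # peak/mean velocity ratio of a minimum-jerk stroke


def _minjerk(u: np.ndarray) -> np.ndarray:
    return 10 * u**3 - 15 * u**4 + 6 * u**5


@dataclass(frozen=True)
class ReachSpec:
    """One scheduled reaching attempt."""

    side: str
    start: int
    out_frames: int
    back_frames: int
    target_well: int  # 1..8
    outcome: str  # no_contact | success | drop
    carried: bool = False  # success only: pellet visibly carried
    grab_offset: tuple[float, float] = (0.0, 0.0)

    @property
    def end(self) -> int:
        return self.start + self.out_frames + self.back_frames

    @property
    def inversion(self) -> int:
        return self.start + self.out_frames


@dataclass(frozen=True)
class SlipSpec:
    """One scheduled forepaw slip off the platform."""

    side: str
    start: int
    down_frames: int
    up_frames: int
    depth_px: float

    @property
    def end(self) -> int:
        return self.start + self.down_frames + self.up_frames


@dataclass(frozen=True)
class SessionSpec:
    """Complete recipe for one synthetic session."""

    seed: int
    n_frames: int
    reaches: tuple[ReachSpec, ...]
    slips: tuple[SlipSpec, ...]
    chamber: ChamberConfig = field(default_factory=default_config)
    fps: float = 100.0
    noise_sd: float = 1.0          # px, paw coordinate noise
    pellet_jitter: float = 0.7     # px, pellet coordinate noise
    spike_rate: float = 2.0        # spikes per 1000 frames per paw
    dropout_rate: float = 2.0      # dropouts per 1000 frames per paw
    occlusion_frames: int = 3      # pellet-likelihood dip length
    occlusion_likelihood: float = 0.4
    carry_frames: int = 7          # visible carry after a carried success
    drop_delay: int = 8            # frames from removal to re-acquisition
    drop_visible: int = 20         # frames the falling pellet stays tracked

    def __post_init__(self) -> None:
        for rate in (self.spike_rate, self.dropout_rate, self.noise_sd):
            if rate < 0:
                raise ValueError("rates and noise_sd must be >= 0")
        for side in ("left", "right"):
            evs = sorted(
                [(r.start, r.end) for r in self.reaches if r.side == side]
                + [(s.start, s.end) for s in self.slips if s.side == side]
            )
            for (s0, e0), (s1, _) in zip(evs, evs[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"overlapping {side} events at frames {s1} < {e0}"
                    )
            if evs and evs[-1][1] > self.n_frames:
                raise ValueError("event schedule exceeds n_frames")


@dataclass
class GroundTruthLog:
    """Exhaustive record of what was injected into a session.

    ``events`` has one row per reach/slip with true frame bounds,
    target well, outcome, removal/drop frames and true kinematics;
    ``artifacts`` lists injected spikes and dropouts per landmark.
    """

    events: pd.DataFrame
    artifacts: pd.DataFrame

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.events.to_csv(path, sep="\t", index=False)
        self.artifacts.to_csv(
            path.with_suffix(".artifacts.tsv"), sep="\t", index=False
        )

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruthLog":
        path = Path(path)
        events = pd.read_csv(path, sep="\t")
        apath = path.with_suffix(".artifacts.tsv")
        artifacts = (
            pd.read_csv(apath, sep="\t") if apath.exists() else pd.DataFrame()
        )
        return cls(events=events, artifacts=artifacts)


def default_session_spec(
    seed: int,
    *,
    n_reaches: int = 50,
    n_slips: int = 10,
    n_success: int = 5,
    n_drop: int = 2,
    noise_sd: float = 1.0,
    spike_rate: float = 2.0,
    dropout_rate: float = 2.0,
    bradykinesia_factor: float = 1.0,
    carried_prob: float = 0.3,
    chamber: ChamberConfig | None = None,
) -> SessionSpec:
    """Draw a randomized default session schedule.

    Per side: ``n_reaches`` reaches (peak outward speed 4-9 px/frame,
    out/back asymmetry 0.35-0.5, targets spread over the staircase) and
    ``n_slips`` slips (depth 22-42 px), in random order with 40-120
    rest frames between events. ``n_success + n_drop`` of the reaches
    contact distinct wells; ``bradykinesia_factor`` multiplies every
    event duration, emulating post-stroke slowing of movement.
    """
    if n_success + n_drop > 8:
        raise ValueError("at most 8 pellet contacts per side")
    rng = np.random.default_rng(seed)
    chamber = chamber or default_config()
    reaches: list[ReachSpec] = []
    slips: list[SlipSpec] = []
    session_end = 0
    for side in ("left", "right"):
        layout = chamber.layout(side)
        rest = np.array(REST_POSITIONS[side])
        kinds = ["reach"] * n_reaches + ["slip"] * n_slips
        rng.shuffle(kinds)
        contact_wells = rng.choice(8, size=n_success + n_drop, replace=False) + 1
        outcome_pool = ["success"] * n_success + ["drop"] * n_drop
        contact_idx = sorted(
            rng.choice(n_reaches, size=len(outcome_pool), replace=False)
        )
        contact_map = dict(zip(contact_idx, zip(contact_wells, outcome_pool)))
        t = int(rng.integers(60, 140))
        reach_i = 0
        for kind in kinds:
            if kind == "reach":
                if reach_i in contact_map:
                    well, outcome = contact_map[reach_i]
                    well, outcome = int(well), str(outcome)
                else:
                    well, outcome = int(rng.integers(1, 9)), "no_contact"
                target = np.array(layout.well_centers[well - 1])
                target = target + rng.normal(0.0, 1.5, size=2)
                dist = float(np.hypot(*(target - rest)))
                v_peak = rng.uniform(4.0, 9.0)
                alpha = rng.uniform(0.35, 0.5)
                out_f = max(8, round(_MJ_PEAK * dist / v_peak))
                back_f = max(10, round(out_f * (1 - alpha) / alpha))
                out_f = max(3, round(out_f * bradykinesia_factor))
                back_f = max(3, round(back_f * bradykinesia_factor))
                reaches.append(
                    ReachSpec(
                        side=side,
                        start=t,
                        out_frames=out_f,
                        back_frames=back_f,
                        target_well=well,
                        outcome=outcome,
                        carried=(
                            outcome == "success"
                            and rng.random() < carried_prob
                        ),
                        grab_offset=tuple(target - layout.well_centers[well - 1]),
                    )
                )
                t += out_f + back_f
                reach_i += 1
            else:
                down = int(rng.integers(8, 13))
                up = int(rng.integers(8, 13))
                down = max(3, round(down * bradykinesia_factor))
                up = max(3, round(up * bradykinesia_factor))
                slips.append(
                    SlipSpec(
                        side=side,
                        start=t,
                        down_frames=down,
                        up_frames=up,
                        depth_px=float(rng.uniform(22.0, 42.0)),
                    )
                )
                t += down + up
            t += int(rng.integers(40, 120))
        session_end = max(session_end, t)
    return SessionSpec(
        seed=seed,
        n_frames=session_end + 100,
        reaches=tuple(reaches),
        slips=tuple(slips),
        chamber=chamber,
        noise_sd=noise_sd,
        spike_rate=spike_rate,
        dropout_rate=dropout_rate,
    )


def _paw_trace(
    spec: SessionSpec, side: str, layout
) -> tuple[np.ndarray, list[dict]]:
    """Noise-free paw trajectory for one side plus per-event truth."""
    n = spec.n_frames
    rest = np.array(REST_POSITIONS[side])
    xy = np.tile(rest, (n, 1))
    truth: list[dict] = []
    for r in (e for e in spec.reaches if e.side == side):
        target = np.array(layout.well_centers[r.target_well - 1]) + np.array(
            r.grab_offset
        )
        delta = target - rest
        dist = float(np.hypot(*delta))
        u_out = np.arange(r.out_frames + 1) / r.out_frames
        u_back = np.arange(1, r.back_frames + 1) / r.back_frames
        profile = np.concatenate([_minjerk(u_out), 1 - _minjerk(u_back)])
        frames = np.arange(r.start, r.end + 1)
        xy[frames] = rest + profile[:, None] * delta
        truth.append(
            {
                "side": side,
                "kind": "reach",
                "start": r.start,
                "inversion": r.inversion,
                "end": r.end + 1,  # half-open: stroke occupies [start, end]
                "target_well": r.target_well,
                "outcome": r.outcome,
                "removal_frame": (
                    r.inversion if r.outcome in ("success", "drop") else -1
                ),
                "drop_frame": (
                    r.inversion + spec.drop_delay if r.outcome == "drop" else -1
                ),
                "depth_px": np.nan,
                "peak_speed_px": _MJ_PEAK
                * dist
                / min(r.out_frames, r.back_frames),
                "path_px": 2.0 * dist,
                "duration_s": (r.out_frames + r.back_frames) / spec.fps,
            }
        )
    for s in (e for e in spec.slips if e.side == side):
        down = np.arange(s.down_frames + 1) / s.down_frames
        up = np.arange(1, s.up_frames + 1) / s.up_frames
        profile = np.concatenate([_minjerk(down), 1 - _minjerk(up)])
        frames = np.arange(s.start, s.end + 1)
        xy[frames, 1] = rest[1] + profile * s.depth_px
        truth.append(
            {
                "side": side,
                "kind": "slip",
                "start": s.start,
                "inversion": -1,
                "end": s.end + 1,
                "target_well": -1,
                "outcome": "n/a",
                "removal_frame": -1,
                "drop_frame": -1,
                "depth_px": s.depth_px,
                "peak_speed_px": _MJ_PEAK * s.depth_px / min(s.down_frames, s.up_frames),
                "path_px": 2.0 * s.depth_px,
                "duration_s": (s.down_frames + s.up_frames) / spec.fps,
            }
        )
    return xy, truth


def _pellet_traces(
    spec: SessionSpec, side: str, layout, paw_xy: np.ndarray, rng
) -> tuple[np.ndarray, np.ndarray]:
    """(n, 8, 2) pellet coordinates and (n, 8) likelihoods for one side."""
    n = spec.n_frames
    xy = np.empty((n, 8, 2))
    lik = np.empty((n, 8))
    for w in range(8):
        center = np.array(layout.well_centers[w])
        xy[:, w] = center + rng.normal(0.0, spec.pellet_jitter, size=(n, 2))
        lik[:, w] = np.clip(1.0 - np.abs(rng.normal(0.0, 0.002, size=n)), 0, 1)

    reaches = sorted(
        (r for r in spec.reaches if r.side == side), key=lambda r: r.start
    )
    for i, r in enumerate(reaches):
        w = r.target_well - 1
        # occlusion dip while the paw is over the well
        d0 = max(r.start, r.inversion - 2 - spec.occlusion_frames)
        d1 = max(d0 + 1, r.inversion - 2)
        lik[d0:d1, w] = spec.occlusion_likelihood
        if r.outcome == "no_contact":
            continue
        removal = r.inversion
        lik[removal:, w] = np.clip(
            np.abs(rng.normal(0.0, 0.03, size=n - removal)), 0, 0.5
        )
        center = np.array(layout.well_centers[w])
        if r.outcome == "drop":
            f0 = removal + spec.drop_delay
            f1 = min(f0 + spec.drop_visible, n)
            tau = np.arange(f1 - f0, dtype=float)
            fall = np.column_stack(
                [
                    center[0] + 0.8 * tau * (1 if side == "right" else -1),
                    np.minimum(center[1] + 12.0 + 0.5 * tau**2, 215.0),
                ]
            )
            xy[f0:f1, w] = fall + rng.normal(0.0, spec.pellet_jitter, fall.shape)
            lik[f0:f1, w] = np.clip(
                1.0 - np.abs(rng.normal(0.0, 0.002, size=f1 - f0)), 0, 1
            )
        elif r.carried:
            f0 = removal
            f1 = min(removal + spec.carry_frames, n)
            xy[f0:f1, w] = paw_xy[f0:f1] + np.array([0.0, 4.0])
            lik[f0:f1, w] = np.clip(
                1.0 - np.abs(rng.normal(0.0, 0.002, size=f1 - f0)), 0, 1
            )
    return xy, lik


def inject_artifacts(
    xy: np.ndarray,
    lik: np.ndarray,
    spec: SessionSpec,
    rng: np.random.Generator,
    landmark: str,
) -> list[dict]:
    """Inject single-frame spikes and dropouts into one paw trace.

    Spikes displace the coordinate by 30-80 px in a random direction
    for one frame (the tracker locking onto the wrong object); dropouts
    zero the likelihood for one frame (lost landmark). Counts are
    Poisson with the spec's per-1000-frame rates; artifact frames are
    kept non-adjacent so every injected defect really is the
    single-frame glitch the cleaning stage is specified to repair.
    Mutates ``xy`` and ``lik`` in place and returns the artifact
    records.
    """
    n = len(xy)
    records: list[dict] = []
    n_spikes = int(rng.poisson(spec.spike_rate * n / 1000.0))
    n_drops = int(rng.poisson(spec.dropout_rate * n / 1000.0))
    occupied: set[int] = set()

    def _pick(count: int) -> list[int]:
        chosen: list[int] = []
        for f in rng.permutation(np.arange(1, n - 1)):
            if len(chosen) == count:
                break
            f = int(f)
            if {f - 1, f, f + 1} & occupied:
                continue
            occupied.add(f)
            chosen.append(f)
        return sorted(chosen)

    for f in _pick(n_spikes):
        theta = rng.uniform(0, 2 * np.pi)
        radius = rng.uniform(30.0, 80.0)
        xy[f] += radius * np.array([np.cos(theta), np.sin(theta)])
        records.append({"landmark": landmark, "frame": f, "kind": "spike"})
    for f in _pick(n_drops):
        lik[f] = 0.0
        records.append({"landmark": landmark, "frame": f, "kind": "dropout"})
    return records


def generate_session(
    spec: SessionSpec,
) -> tuple[TrajectoryTable, GroundTruthLog]:
    """Render a session spec into a trajectory table plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    landmarks: list[str] = []
    cols_x, cols_y, cols_l = [], [], []
    truth_rows: list[dict] = []
    artifact_rows: list[dict] = []

    for side in ("left", "right"):
        layout = spec.chamber.layout(side)
        paw_xy, truth = _paw_trace(spec, side, layout)
        truth_rows.extend(truth)
        pellet_xy, pellet_lik = _pellet_traces(spec, side, layout, paw_xy, rng)
        paw_xy = paw_xy + rng.normal(0.0, spec.noise_sd, size=paw_xy.shape)
        paw_lik = np.clip(1.0 - np.abs(rng.normal(0.0, 0.004, size=n)), 0, 1)
        artifact_rows.extend(
            inject_artifacts(paw_xy, paw_lik, spec, rng, layout.paw_landmark)
        )
        landmarks.append(layout.paw_landmark)
        cols_x.append(paw_xy[:, 0])
        cols_y.append(paw_xy[:, 1])
        cols_l.append(paw_lik)
        for w, name in enumerate(layout.well_names):
            landmarks.append(name)
            cols_x.append(pellet_xy[:, w, 0])
            cols_y.append(pellet_xy[:, w, 1])
            cols_l.append(pellet_lik[:, w])

    table = TrajectoryTable(
        landmarks=landmarks,
        x=np.column_stack(cols_x),
        y=np.column_stack(cols_y),
        likelihood=np.column_stack(cols_l),
        fps=spec.fps,
    )
    events = pd.DataFrame(truth_rows).sort_values(
        ["side", "start"], kind="stable"
    )
    artifacts = pd.DataFrame(
        artifact_rows, columns=["landmark", "frame", "kind"]
    )
    return table, GroundTruthLog(events=events.reset_index(drop=True), artifacts=artifacts)


def generate_cohort(
    n_animals: int,
    phenotype: str,
    seed: int,
    *,
    days: tuple[str, ...] = ("pre", "p21"),
    bradykinesia_factor: float = 1.5,
    slip_multiplier: float = 2.5,
) -> list[dict]:
    """Simulate a cohort of animals across recording days.

    Phenotypes emulate the qualitative post-stroke pictures seen in the
    Staircase: ``mcao_like`` (striatal stroke) slows reaching movements
    progressively (durations scaled up to ``bradykinesia_factor`` on
    the last day); ``pt_like`` (cortical stroke) multiplies the slip
    count and converts successes into drops; ``sham`` is stationary.
    Returns one record per animal-day: ``{animal, day, spec}``.
    """
    if phenotype not in ("sham", "mcao_like", "pt_like"):
        raise ValueError(f"unknown phenotype {phenotype!r}")
    out: list[dict] = []
    n_days = len(days)
    for a in range(n_animals):
        for d, day in enumerate(days):
            post = day != "pre"
            frac = d / max(n_days - 1, 1)
            factor = 1.0
            n_slips, n_success, n_drop = 10, 5, 2
            if phenotype == "mcao_like" and post:
                factor = 1.0 + (bradykinesia_factor - 1.0) * frac
            if phenotype == "pt_like" and post:
                n_slips = int(round(10 * slip_multiplier))
                n_success, n_drop = 2, 4
            sub_seed = (seed * 1_000_003 + a * 101 + d) % (2**31)
            out.append(
                {
                    "animal": f"{phenotype}_{a:02d}",
                    "day": day,
                    "spec": default_session_spec(
                        sub_seed,
                        n_slips=n_slips,
                        n_success=n_success,
                        n_drop=n_drop,
                        bradykinesia_factor=factor,
                    ),
                }
            )
    return out
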