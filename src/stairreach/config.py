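"""Chamber geometry and analysis configuration.

A Staircase chamber is described by the pixel positions of its eight
pellet wells per body side, the vertical coordinate of the stabilizing
platform edge, a pixel-per-centimetre scale and the video frame rate.
All coordinates use image convention: the origin is the top-left pixel
centre and y grows downward, so "the paw drops below the platform"
means y increasing past ``platform_y``.

Analysis thresholds (velocity threshold, slip ratio, jump rejection
multiplier, smoothing window, pellet-probability threshold, ...) live in
:class:`AnalysisConfig`; every one of them can be overridden from the
YAML config file or from the command line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

SIDES = ("left", "right")

#: landmark naming convention used throughout the package
PAW_LANDMARKS = {"left": "paw_left", "right": "paw_right"}


def well_landmark(side: str, well: int) -> str:
    """Name of the pellet landmark for ``well`` (1-based) on ``side``."""
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    if not 1 <= well <= 8:
        raise ValueError(f"well index {well} outside 1..8")
    return f"well_{side[0]}{well}"


def well_landmarks(side: str) -> list[str]:
    return [well_landmark(side, w) for w in range(1, 9)]


@dataclass(frozen=True)
class ChamberLayout:
    """Geometry of one side of a single reaching chamber.

    Parameters
    ----------
    side
        ``"left"`` or ``"right"``.
    well_centers
        Eight (x, y) pixel positions of the staircase wells, ordered
        well 1..8 from top step to bottom step.
    platform_y
        Vertical pixel coordinate of the stabilizing platform edge.
    px_per_cm
        Scale factor converting pixels to centimetres.
    fps
        Video frame rate in frames per second.
    """

    side: str
    well_centers: tuple[tuple[float, float], ...]
    platform_y: float
    px_per_cm: float
    fps: float

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if len(self.well_centers) != 8:
            raise ValueError(
                f"expected 8 well centers, got {len(self.well_centers)}"
            )
        object.__setattr__(
            self,
            "well_centers",
            tuple((float(x), float(y)) for x, y in self.well_centers),
        )
        if len(set(self.well_centers)) != 8:
            raise ValueError("well centers must be pairwise distinct")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def paw_landmark(self) -> str:
        return PAW_LANDMARKS[self.side]

    @property
    def well_names(self) -> list[str]:
        return well_landmarks(self.side)

    def required_landmarks(self) -> list[str]:
        return [self.paw_landmark, *self.well_names]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable thresholds of the processing pipeline.

    Defaults implement the published processing rules: a 6x-SD jump
    filter, single-frame gap filling, a 10-frame moving mean, a
    1.5 px/frame velocity threshold for event candidates, a 1.5
    horizontal/vertical displacement ratio separating reaches from
    slips, and a 99 % pellet-existence probability threshold.
    """

    velocity_threshold: float = 1.5      # px/frame, candidate extrema
    slip_ratio_threshold: float = 1.5    # dimensionless, dx/dy
    jump_sd_multiplier: float = 6.0      # SD multiples for jump rejection
    smoothing_window: int = 10           # frames, centred moving mean
    pellet_prob_threshold: float = 0.99  # pellet-existence probability
    max_gap_fill: int = 1                # frames, longest fillable gap
    removal_debounce: int = 5            # frames below threshold before
                                         # a removal becomes provisional
    paw_likelihood_floor: float = 0.6    # paw frames below are invalid
    zero_band_px: float = 0.15           # px/frame; |v| below this counts
                                         # as zero when locating the
                                         # zero crossings bounding an event
    min_event_frames: int = 3            # shortest admissible event
    platform_band_px: float = 15.0       # slip must start within this
                                         # band around platform_y
    well_radius_px: float = 10.0         # spatial extent of a well
    divergence_px: float = 15.0          # pellet-paw separation => drop
    event_match_tolerance: int = 10      # frames, validation matching

    def __post_init__(self) -> None:
        for name in (
            "velocity_threshold",
            "slip_ratio_threshold",
            "jump_sd_multiplier",
            "smoothing_window",
            "max_gap_fill",
            "removal_debounce",
            "min_event_frames",
            "platform_band_px",
            "well_radius_px",
            "divergence_px",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.pellet_prob_threshold < 1.0:
            raise ValueError("pellet_prob_threshold must be in (0, 1)")
        if not 0.0 <= self.paw_likelihood_floor < 1.0:
            raise ValueError("paw_likelihood_floor must be in [0, 1)")
        if not 0.0 <= self.zero_band_px < self.velocity_threshold:
            raise ValueError("zero_band_px must be in [0, velocity_threshold)")
        if self.event_match_tolerance < 0:
            raise ValueError("event_match_tolerance must be >= 0")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ChamberConfig:
    """Full per-chamber configuration: both side layouts + thresholds."""

    layouts: dict[str, ChamberLayout]
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        for side, layout in self.layouts.items():
            if layout.side != side:
                raise ValueError(
                    f"layout registered under {side!r} has side {layout.side!r}"
                )

    @property
    def sides(self) -> list[str]:
        return [s for s in SIDES if s in self.layouts]

    def layout(self, side: str) -> ChamberLayout:
        return self.layouts[side]

    def to_dict(self) -> dict:
        return {
            "chamber": {
                side: {
                    "well_centers": [list(c) for c in lay.well_centers],
                    "platform_y": lay.platform_y,
                    "px_per_cm": lay.px_per_cm,
                    "fps": lay.fps,
                }
                for side, lay in self.layouts.items()
            },
            "analysis": dataclasses.asdict(self.analysis),
        }

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> ChamberConfig:
    """Load a :class:`ChamberConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "chamber" not in raw:
        raise ValueError(f"{path}: missing 'chamber' section")
    layouts = {}
    for side, sec in raw["chamber"].items():
        layouts[side] = ChamberLayout(
            side=side,
            well_centers=tuple(tuple(c) for c in sec["well_centers"]),
            platform_y=float(sec["platform_y"]),
            px_per_cm=float(sec["px_per_cm"]),
            fps=float(sec["fps"]),
        )
    analysis = AnalysisConfig(**raw.get("analysis", {}))
    return ChamberConfig(layouts=layouts, analysis=analysis)


def save_config(config: ChamberConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def default_layout(
    side: str,
    *,
    fps: float = 100.0,
    px_per_cm: float = 40.0,
    platform_y: float = 70.0,
) -> ChamberLayout:
    """Staircase geometry used by the simulator: 8 wells stepping away
    from the central platform inside a 320 x 240 px chamber image,
    seen from the side. Successive wells sit further out horizontally
    and slightly lower (the staircase descends), so reaching is a
    predominantly horizontal movement while slipping off the platform
    edge is vertical. Left-side wells step out to the left of the
    frame, right-side wells mirrored to the right.
    """
    ys = [72.0 + 6.0 * k for k in range(8)]
    if side == "left":
        xs = [120.0 - 16.0 * k for k in range(8)]
    elif side == "right":
        xs = [200.0 + 16.0 * k for k in range(8)]
    else:
        raise ValueError(f"unknown side {side!r}")
    return ChamberLayout(
        side=side,
        well_centers=tuple(zip(xs, ys)),
        platform_y=platform_y,
        px_per_cm=px_per_cm,
        fps=fps,
    )


def default_config(**analysis_overrides) -> ChamberConfig:
    """Default two-sided chamber config matching the simulator geometry."""
    return ChamberConfig(
        layouts={s: default_layout(s) for s in SIDES},
        analysis=AnalysisConfig(**analysis_overrides),
    )
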