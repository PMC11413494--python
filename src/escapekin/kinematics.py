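"""Ballistic reconstruction of evasive jumps and frame/time conversions.

A rodent's evasive leap is treated as level-ground projectile motion: the
animal leaves and lands at the same height, so the horizontal displacement
``d`` (metres, measured between take-off and landing positions) and the
airborne time ``t`` (seconds, between the take-off and landing frames)
determine the take-off velocity vector completely:

    v_h   = d / t                     horizontal velocity
    v_v   = g * t / 2                 vertical take-off velocity
    speed = sqrt(v_h**2 + v_v**2)     take-off speed
    angle = atan(v_v / v_h) * 180/pi  take-off angle, degrees
    h     = v_v**2 / (2 g)            jump height (apex above take-off)

with g = 9.8 m s^-2. ``forward_ballistics`` is the exact inverse and is used
by the trial simulator. Timing utilities convert high-speed-video frame
indices (120-250 fps recordings) into the millisecond reaction and take-off
intervals the analyses use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "G_STANDARD",
    "JumpObservation",
    "JumpKinematics",
    "FrameClock",
    "compute_kinematics",
    "forward_ballistics",
    "frames_to_ms",
    "downsample_frames",
    "timing_from_frames",
]

#: Acceleration due to gravity used throughout, m s^-2.
G_STANDARD = 9.8


@dataclass(frozen=True)
class JumpObservation:
    """What the field protocol measures for one jump.

    Parameters
    ----------
    horizontal_displacement_m
        Tape-measure distance between take-off and landing positions, metres.
    airborne_time_s
        Seconds between the take-off and landing frames; must be positive.
    """

    horizontal_displacement_m: float
    airborne_time_s: float

    def __post_init__(self) -> None:
        if not self.airborne_time_s > 0:
            raise ValueError(
                f"airborne_time_s must be > 0, got {self.airborne_time_s!r}"
            )
        if self.horizontal_displacement_m < 0:
            raise ValueError(
                "horizontal_displacement_m must be >= 0, got "
                f"{self.horizontal_displacement_m!r}"
            )


@dataclass(frozen=True)
class JumpKinematics:
    """Take-off velocity vector and derived jump performance metrics."""

    v_horizontal: float
    v_vertical: float
    takeoff_speed: float
    takeoff_angle_deg: float
    jump_height_m: float
    g: float = G_STANDARD


@dataclass(frozen=True)
class FrameClock:
    """Frame rate of a recording and the implied frame period."""

    fps: float
    frame_period_ms: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps!r}")
        object.__setattr__(self, "frame_period_ms", 1000.0 / self.fps)


def compute_kinematics(obs: JumpObservation, g: float = G_STANDARD) -> JumpKinematics:
    """Reconstruct the take-off velocity vector from one jump observation.

    A zero horizontal displacement is the purely vertical jump and yields a
    90 degree take-off angle rather than an error.
    """
    d = obs.horizontal_displacement_m
    t = obs.airborne_time_s
    v_h = d / t
    v_v = g * t / 2.0
    speed = math.hypot(v_h, v_v)
    # atan2 gives the vertical-jump limit (v_h == 0 -> 90 deg) for free
    angle = math.degrees(math.atan2(v_v, v_h))
    height = v_v**2 / (2.0 * g)
    return JumpKinematics(
        v_horizontal=v_h,
        v_vertical=v_v,
        takeoff_speed=speed,
        takeoff_angle_deg=angle,
        jump_height_m=height,
        g=g,
    )


def forward_ballistics(
    speed: float, angle_deg: float, g: float = G_STANDARD
) -> JumpObservation:
    """Project a take-off (speed, angle) forward to displacement and hang time.

    Exact inverse of :func:`compute_kinematics` for level take-off/landing:
    ``t = 2 v sin(theta) / g`` and ``d = v cos(theta) t``.
    """
    if not speed > 0:
        raise ValueError(f"speed must be > 0, got {speed!r}")
    if not 0 < angle_deg <= 90:
        raise ValueError(f"angle_deg must be in (0, 90], got {angle_deg!r}")
    theta = math.radians(angle_deg)
    t = 2.0 * speed * math.sin(theta) / g
    d = speed * math.cos(theta) * t
    # cos(90 deg) is ~6e-17, not 0; clamp so the vertical jump is exact
    if angle_deg == 90:
        d = 0.0
    return JumpObservation(horizontal_displacement_m=d, airborne_time_s=t)


def frames_to_ms(frames: float, fps: float) -> float:
    """Convert a frame count at ``fps`` into milliseconds (1 frame = 1000/fps ms)."""
    if not fps > 0:
        raise ValueError(f"fps must be > 0, got {fps!r}")
    if frames < 0:
        raise ValueError(f"frames must be >= 0, got {frames!r}")
    return frames * 1000.0 / fps


def downsample_frames(frame_indices, source_fps: float, target_fps: float):
    """Map frame indices at ``source_fps`` to indices at a lower ``target_fps``.

    The source rate must be an integer multiple of the target rate (e.g. the
    500 fps recordings down-sampled to 250 fps); index ``i`` maps to
    ``i // factor``, which preserves every event time to within one
    target-frame period and never reorders events.
    """
    factor = source_fps / target_fps
    if factor != int(factor) or factor < 1:
        raise ValueError(
            f"source_fps ({source_fps}) must be an integer multiple of "
            f"target_fps ({target_fps})"
        )
    idx = np.asarray(frame_indices)
    if np.any(idx < 0):
        raise ValueError("frame indices must be non-negative")
    out = idx // int(factor)
    return int(out) if np.isscalar(frame_indices) else out


def timing_from_frames(
    cork_frame: int,
    reaction_frame: int,
    toeoff_frame: int,
    clock: FrameClock,
) -> tuple[float, float, float]:
    """Reaction, take-off and overall response times (ms) from event frames.

    Reaction time spans first cork movement to the rodent's first visible
    movement; take-off time spans that first movement to the frame preceding
    toe-off; overall response time is their sum. A reaction frame before the
    cork frame is the "premature reaction" case and is rejected — such trials
    are censored, not timed.
    """
    if not cork_frame <= reaction_frame <= toeoff_frame:
        raise ValueError(
            "frames must satisfy cork <= reaction <= toe-off, got "
            f"({cork_frame}, {reaction_frame}, {toeoff_frame})"
        )
    period = clock.frame_period_ms
    reaction_ms = (reaction_frame - cork_frame) * period
    takeoff_ms = (toeoff_frame - reaction_frame) * period
    return reaction_ms, takeoff_ms, reaction_ms + takeoff_ms
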