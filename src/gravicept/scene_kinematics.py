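"""Virtual scene geometry and target kinematics.

A ball is released from a fixed height above a supine observer and drops
vertically toward an interception ring held just above the observer's head.
Twelve kinematic conditions are formed by crossing three acceleration
profiles (downward 9.8 m/s², constant velocity, decelerating 9.8 m/s²) with
four motion durations; within each duration the initial velocity is chosen
so that the mean velocity (drop distance / duration) is identical across
acceleration profiles.

Conventions: downward is the positive axis, so the decelerating profile has
a = -9.8 m/s² applied to the downward speed. Distances for interception are
ball-to-ring; distances for retinal variables are ball-to-eye (the eye sits
``eye_ring_offset`` metres below the ring).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SceneGeometry",
    "MotionCondition",
    "KinematicState",
    "RetinalTrace",
    "LABELS",
    "DURATIONS",
    "drop_distance",
    "label_acceleration",
    "solve_initial_velocity",
    "build_condition_table",
    "state_at",
    "retinal_trace",
    "conditions_to_frame",
    "write_condition_csv",
    "read_condition_csv",
]

#: Acceleration labels in the fixed ordering used throughout the package.
LABELS = ("minus_g", "zero_g", "plus_g")

#: Motion durations in seconds, longest first (the printed table ordering).
DURATIONS = (1.1, 1.0, 0.9, 0.8)

_LABEL_SIGN = {"minus_g": -1.0, "zero_g": 0.0, "plus_g": 1.0}


@dataclass(frozen=True)
class SceneGeometry:
    """Fixed lengths of the virtual scene, in real-world metres.

    Attributes
    ----------
    release_height : float
        Height of the release point above the ground (m).
    ring_height : float
        Height of the interception ring above the ground (m).
    ball_diameter : float
        Physical diameter of the ball (m).
    eye_ring_offset : float
        Vertical distance from the observer's eye up to the ring (m).
    disappearance_offset : float
        Distance below the ring at which the ball vanishes from view (m).
    g : float
        Gravitational acceleration magnitude (m/s²).
    """

    release_height: float = 9.72
    ring_height: float = 0.775
    ball_diameter: float = 0.07
    eye_ring_offset: float = 0.5
    disappearance_offset: float = 0.40
    g: float = 9.8

    def __post_init__(self) -> None:
        if not (self.release_height > self.ring_height > 0):
            raise ValueError("require release_height > ring_height > 0")
        for name in ("ball_diameter", "eye_ring_offset", "disappearance_offset", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def drop_distance(self) -> float:
        """Release-to-ring distance (m)."""
        return self.release_height - self.ring_height

    def replace(self, **kwargs) -> "SceneGeometry":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MotionCondition:
    """One of the 12 target kinematic profiles.

    ``acceleration`` is the signed downward acceleration in m/s²;
    ``v0``/``vt`` are the downward speeds at motion onset and at the ring.
    """

    label: str
    duration: float
    v0: float
    vt: float
    acceleration: float

    @property
    def key(self) -> tuple[str, float]:
        return (self.label, self.duration)


@dataclass(frozen=True)
class KinematicState:
    """Ball state at time ``t`` after motion onset."""

    t: float
    distance_to_ring: float
    velocity: float


@dataclass(frozen=True)
class RetinalTrace:
    """Sampled retinal angular size theta (rad) and dilation rate (rad/s)."""

    times: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray


def drop_distance(geometry: SceneGeometry) -> float:
    """Distance from the release point to the interception ring (m)."""
    return geometry.drop_distance


def label_acceleration(label: str, geometry: SceneGeometry) -> float:
    """Signed downward acceleration (m/s²) for an acceleration label."""
    try:
        return _LABEL_SIGN[label] * geometry.g
    except KeyError:
        raise ValueError(f"unknown acceleration label {label!r}") from None


def solve_initial_velocity(label: str, duration: float, geometry: SceneGeometry) -> float:
    """Initial downward speed so the ball covers the drop in ``duration`` s.

    Closed form of D = v0*T + a*T²/2:  v0 = (D - a*T²/2) / T.  Raises if the
    resulting onset or terminal speed is not positive (the ball would stall
    or reverse before reaching the ring).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    a = label_acceleration(label, geometry)
    d = geometry.drop_distance
    v0 = (d - 0.5 * a * duration**2) / duration
    vt = v0 + a * duration
    if v0 <= 0 or vt <= 0:
        raise ValueError(
            f"unphysical condition {label}/{duration}: v0={v0:.3f}, vt={vt:.3f}"
        )
    return v0


def build_condition_table(geometry: SceneGeometry | None = None) -> list[MotionCondition]:
    """The 12 motion conditions (3 accelerations x 4 durations).

    Ordered by label (minus_g, zero_g, plus_g) then duration descending,
    matching the printed condition-table layout.
    """
    geometry = geometry or SceneGeometry()
    out = []
    for label in LABELS:
        a = label_acceleration(label, geometry)
        for duration in DURATIONS:
            v0 = solve_initial_velocity(label, duration, geometry)
            out.append(
                MotionCondition(
                    label=label,
                    duration=duration,
                    v0=v0,
                    vt=v0 + a * duration,
                    acceleration=a,
                )
            )
    return out


def state_at(condition: MotionCondition, t: float, geometry: SceneGeometry | None = None) -> KinematicState:
    """Exact ball state at time ``t`` in [0, T] after motion onset."""
    geometry = geometry or SceneGeometry()
    if not (0.0 <= t <= condition.duration + 1e-12):
        raise ValueError(f"t={t} outside [0, {condition.duration}]")
    a = condition.acceleration
    dist = geometry.drop_distance - (condition.v0 * t + 0.5 * a * t**2)
    return KinematicState(t=t, distance_to_ring=max(dist, 0.0), velocity=condition.v0 + a * t)


def retinal_trace(
    condition: MotionCondition,
    geometry: SceneGeometry | None = None,
    dt: float = 1e-3,
) -> RetinalTrace:
    """Retinal image size and dilation rate sampled every ``dt`` seconds.

    theta(t) = 2*atan(s / (2*d_eye)) with d_eye the eye-to-ball distance
    (ball-to-ring distance plus the eye-to-ring offset); theta_dot is the
    analytic derivative s*v / (d_eye² + s²/4).
    """
    geometry = geometry or SceneGeometry()
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = geometry.ball_diameter
    times = np.arange(0.0, condition.duration + dt / 2, dt)
    times[-1] = min(times[-1], condition.duration)
    a = condition.acceleration
    dist_ring = geometry.drop_distance - (condition.v0 * times + 0.5 * a * times**2)
    d_eye = dist_ring + geometry.eye_ring_offset
    if np.any(d_eye <= 0):
        raise ValueError("eye-to-ball distance reaches zero inside the sampled interval")
    v = condition.v0 + a * times
    theta = 2.0 * np.arctan2(s, 2.0 * d_eye)
    theta_dot = s * v / (d_eye**2 + s**2 / 4.0)
    return RetinalTrace(times=times, theta=theta, theta_dot=theta_dot)


# ---------------------------------------------------------------------------
# Tabular views and round-trip I/O

def conditions_to_frame(conditions: Sequence[MotionCondition], rounded: bool = False) -> pd.DataFrame:
    """DataFrame view (label, duration_s, v0_ms, vt_ms).

    With ``rounded=True`` speeds are rounded to 0.1 m/s, matching the
    printed kinematic table.
    """
    df = pd.DataFrame(
        {
            "label": [c.label for c in conditions],
            "duration_s": [c.duration for c in conditions],
            "v0_ms": [c.v0 for c in conditions],
            "vt_ms": [c.vt for c in conditions],
        }
    )
    if rounded:
        df["v0_ms"] = df["v0_ms"].round(1)
        df["vt_ms"] = df["vt_ms"].round(1)
    return df


def write_condition_csv(conditions: Sequence[MotionCondition], path) -> None:
    conditions_to_frame(conditions).to_csv(path, index=False, float_format="%.17g")


def read_condition_csv(path, geometry: SceneGeometry | None = None) -> list[MotionCondition]:
    geometry = geometry or SceneGeometry()
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        MotionCondition(
            label=row.label,
            duration=float(row.duration_s),
            v0=float(row.v0_ms),
            vt=float(row.vt_ms),
            acceleration=label_acceleration(row.label, geometry),
        )
        for row in df.itertuples()
    ]
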