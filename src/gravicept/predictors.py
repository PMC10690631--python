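"""Arrival-time predictors: gravity-prior extrapolation and the known-size
(KS) optical model.

The *gravity* predictors formalise the hypothesis that, at some engagement
time ``t_e`` after motion onset, the observer extrapolates the remaining
fall as if the ball were accelerated by gravity from its current state —
solving d_rem = v_e*tau + g*tau²/2 for the positive root. A grid of
engagement times (0 to 600 ms every 50 ms) gives thirteen predictors. For
the gravity-congruent (plus_g) conditions the extrapolation coincides with
the true motion, so every gravity predictor returns the true duration.

The *optical* predictor is a known-size looming model: the interceptive
action is triggered when the retinal dilation rate theta_dot = s*v/d²
(small-angle, d = ball-to-ring distance) crosses the threshold
theta_dot_th = s/(v_bar*Tca²), where v_bar is the mean target speed in the
100 ms window 150-250 ms before arrival and Tca is the motor delay of the
button press; the predicted response lands Tca after the crossing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .scene_kinematics import (
    MotionCondition,
    SceneGeometry,
    build_condition_table,
    state_at,
)

__all__ = [
    "KSParams",
    "DEFAULT_ENGAGEMENT_GRID_MS",
    "gravity_arrival_estimate",
    "gravity_predictor_grid",
    "mean_prearrival_velocity",
    "optical_arrival_estimate",
    "build_predictor_table",
    "engagement_column",
    "write_predictor_csv",
    "write_predictor_json",
    "read_predictor_csv",
]

#: Engagement-time grid: motion onset to 600 ms, every 50 ms.
DEFAULT_ENGAGEMENT_GRID_MS: tuple[int, ...] = tuple(range(0, 601, 50))


@dataclass(frozen=True)
class KSParams:
    """Parameters of the known-size optical model.

    tca: motor delay between trigger and button press (s).
    window: (start, end) of the velocity-averaging window, in seconds
        before arrival (the mean speed is taken over [T-end, T-start]).
    """

    tca: float = 0.150
    window: tuple[float, float] = (0.150, 0.250)

    def __post_init__(self) -> None:
        if self.tca <= 0:
            raise ValueError("tca must be positive")
        lo, hi = self.window
        if not (0 <= lo < hi):
            raise ValueError("window must satisfy 0 <= start < end")


def gravity_arrival_estimate(
    condition: MotionCondition,
    t_e: float,
    geometry: SceneGeometry | None = None,
) -> float:
    """Predicted arrival time (ms) assuming 1g motion from ``t_e`` on.

    Returns 1000*(t_e + tau) with tau the positive root of
    d_rem = v_e*tau + g*tau²/2 evaluated at the true state (d_rem, v_e) at
    the engagement time. Gravity-congruent conditions return the true
    duration for any engagement time; so does any condition once
    t_e >= T (the target has already arrived).
    """
    geometry = geometry or SceneGeometry()
    if t_e < 0:
        raise ValueError("engagement time must be non-negative")
    if condition.label == "plus_g" or t_e >= condition.duration:
        return 1000.0 * condition.duration
    state = state_at(condition, t_e, geometry)
    d_rem, v_e = state.distance_to_ring, state.velocity
    if d_rem <= 0 or v_e <= 0:
        return 1000.0 * condition.duration
    g = geometry.g
    disc = v_e**2 + 2.0 * g * d_rem
    assert disc > 0
    tau = (-v_e + math.sqrt(disc)) / g
    return 1000.0 * (t_e + tau)


def gravity_predictor_grid(
    conditions: Sequence[MotionCondition] | None = None,
    grid_ms: Sequence[int] = DEFAULT_ENGAGEMENT_GRID_MS,
    geometry: SceneGeometry | None = None,
) -> pd.DataFrame:
    """Gravity predictors for every condition and engagement time.

    Rows are indexed by (label, duration); columns ``g_000`` ... ``g_600``
    hold predicted arrival times in (unrounded) milliseconds.
    """
    geometry = geometry or SceneGeometry()
    conditions = conditions if conditions is not None else build_condition_table(geometry)
    data = {
        engagement_column(t_ms): [
            gravity_arrival_estimate(c, t_ms / 1000.0, geometry) for c in conditions
        ]
        for t_ms in grid_ms
    }
    index = pd.MultiIndex.from_tuples(
        [c.key for c in conditions], names=["label", "duration"]
    )
    return pd.DataFrame(data, index=index)


def engagement_column(t_ms: int | float) -> str:
    """Column name for an engagement time in ms (``g_450`` for 450 ms)."""
    return f"g_{int(round(t_ms)):03d}"


def mean_prearrival_velocity(
    condition: MotionCondition,
    window: tuple[float, float] = (0.150, 0.250),
) -> float:
    """Time-averaged target speed over the pre-arrival window (m/s).

    The window (start, end) is measured backwards from arrival; for the
    linear speed profiles here the average equals the speed at the window
    midpoint.
    """
    lo, hi = window
    if not (0 <= lo < hi <= condition.duration):
        raise ValueError("averaging window exceeds the trajectory")
    t0, t1 = condition.duration - hi, condition.duration - lo
    # v(t) linear: average over [t0, t1] is v at the midpoint.
    return condition.v0 + condition.acceleration * 0.5 * (t0 + t1)


def optical_arrival_estimate(
    condition: MotionCondition,
    geometry: SceneGeometry | None = None,
    ks: KSParams | None = None,
) -> float:
    """KS-model predicted arrival time (ms).

    Finds the earliest time the small-angle dilation rate s*v(t)/d(t)²
    (d = ball-to-ring distance) reaches the threshold s/(v_bar*tca²), and
    returns the crossing time plus the motor delay, in ms.
    """
    geometry = geometry or SceneGeometry()
    ks = ks or KSParams()
    s = geometry.ball_diameter
    v_bar = mean_prearrival_velocity(condition, ks.window)
    thdot_th = s / (v_bar * ks.tca**2)

    def excess(t: float) -> float:
        st = state_at(condition, t, geometry)
        return s * st.velocity / st.distance_to_ring**2 - thdot_th

    t_hi = condition.duration - 1e-9
    if excess(t_hi) < 0:
        raise ValueError(
            f"dilation-rate threshold never reached for {condition.label}/{condition.duration}"
        )
    if excess(0.0) >= 0:
        t_star = 0.0
    else:
        t_star = brentq(excess, 0.0, t_hi, xtol=1e-12)
    return 1000.0 * (t_star + ks.tca)


def build_predictor_table(
    geometry: SceneGeometry | None = None,
    grid_ms: Sequence[int] = DEFAULT_ENGAGEMENT_GRID_MS,
    ks: KSParams | None = None,
    conditions: Sequence[MotionCondition] | None = None,
) -> pd.DataFrame:
    """Full predictor table: gravity grid columns plus the optical column.

    Values are unrounded milliseconds; round for display only.
    """
    geometry = geometry or SceneGeometry()
    conditions = conditions if conditions is not None else build_condition_table(geometry)
    table = gravity_predictor_grid(conditions, grid_ms, geometry)
    table["optical"] = [
        optical_arrival_estimate(c, geometry, ks) for c in conditions
    ]
    return table


def write_predictor_csv(table: pd.DataFrame, path, rounded: bool = False) -> None:
    """Write the predictor table to CSV (optionally rounded to whole ms)."""
    out = table.round(0).astype(int) if rounded else table
    out.to_csv(path, float_format="%.17g")


def read_predictor_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=["label", "duration"], float_precision="round_trip")


def write_predictor_json(table: pd.DataFrame, path) -> None:
    """Full-precision JSON: {label/duration: {column: ms}}."""
    payload = {
        f"{label}/{duration}": {k: float(v) for k, v in row.items()}
        for (label, duration), row in table.iterrows()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
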