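"""Joint-angle conventions, the constrained kinematic grid, derived metrics.

Two angle conventions coexist:

* the **2D-model** generalized coordinates ``theta_0..theta_3`` of the
  chain, and
* the **MSK** (anatomical) convention with positive ankle dorsiflexion,
  knee extension, hip flexion, lumbar extension and posterior pelvic tilt.

They are related by the linear map

    ankle  = -theta_1
    knee   = -theta_2
    hip    =  theta_2 + theta_1 + theta_0 - pelvic_tilt
    lumbar =  hip + theta_3

Pelvic tilt is an extra anatomical degree of freedom (pelvis orientation
within the lumped trunk link); it shifts how the chain posture is split
between hip and lumbar angles but does not move the four links.

The sit-to-stand state space is the Cartesian grid of Table-1-style
ranges at 5-degree increments with the foot flat (theta_0 = 0), filtered
by the hip-flexion and lumbar-range constraints.  All angles at this
module's interfaces are degrees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .planar_model import SegmentParams, State2D

#: Default grid over the 2D-model coordinates and pelvic tilt, degrees.
DEFAULT_RANGES: dict[str, tuple[int, int]] = {
    "theta1": (-40, 0),
    "theta2": (75, 100),
    "theta3": (-150, -60),
    "pelvic_tilt": (-60, 20),
}
DEFAULT_INCREMENT = 5
#: Anatomical box constraints applied after conversion, degrees.
HIP_RANGE = (15, 120)
LUMBAR_RANGE = (-90, 60)

#: Anatomical (MSK) ranges spanned by the enumerated grid, degrees.
MSK_RANGES: dict[str, tuple[int, int]] = {
    "ankle": (0, 40),
    "knee": (-100, -75),
    "hip": HIP_RANGE,
    "lumbar": LUMBAR_RANGE,
    "pelvic_tilt": (-60, 20),
}

#: Initial sit-to-stand posture of the chain, degrees.
INITIAL_POSITION_DEG = (0.0, 0.0, 90.0, -90.0)

STATE_GRID_COLUMNS = [
    "theta0", "theta1", "theta2", "theta3",
    "ankle", "knee", "hip", "lumbar", "pelvic_tilt",
    "foot_position", "pelvis_height",
]


class EmptyGridError(ValueError):
    """Raised when a grid specification admits no kinematic state."""


@dataclass(frozen=True)
class StateMSK:
    """Anatomical joint angles, degrees (positive per the MSK convention)."""

    ankle: float
    knee: float
    hip: float
    lumbar: float
    pelvic_tilt: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ankle": self.ankle,
            "knee": self.knee,
            "hip": self.hip,
            "lumbar": self.lumbar,
            "pelvic_tilt": self.pelvic_tilt,
        }


@dataclass(frozen=True)
class GridSpec:
    """Ranges (degrees, inclusive), increment, and anatomical constraints."""

    ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    increment: int = DEFAULT_INCREMENT
    hip_range: tuple[int, int] = HIP_RANGE
    lumbar_range: tuple[int, int] = LUMBAR_RANGE

    def axis(self, name: str) -> list[int]:
        lo, hi = self.ranges[name]
        if (hi - lo) % self.increment:
            raise ValueError(
                f"increment {self.increment} does not divide the {name} "
                f"range [{lo}, {hi}]"
            )
        return list(range(lo, hi + 1, self.increment))


def to_msk(state: State2D, pelvic_tilt: float) -> StateMSK:
    """Convert 2D-model coordinates (plus a pelvic tilt, degrees) to MSK angles."""
    t0, t1, t2, t3 = state.degrees
    hip = t2 + t1 + t0 - pelvic_tilt
    return StateMSK(
        ankle=-t1,
        knee=-t2,
        hip=hip,
        lumbar=hip + t3,
        pelvic_tilt=pelvic_tilt,
    )


def from_msk(state: StateMSK) -> tuple[State2D, float]:
    """Exact inverse of :func:`to_msk` under the foot-flat rule theta_0 = 0."""
    t1 = -state.ankle
    t2 = -state.knee
    t3 = state.lumbar - state.hip
    # consistency of the redundant parameterization: tilt = t2 + t1 - hip
    return State2D.from_degrees([0.0, t1, t2, t3]), float(state.pelvic_tilt)


def foot_position(state: StateMSK, params: SegmentParams) -> float:
    """Horizontal ankle-relative-to-hip distance, normalized to leg length.

    The two segment projections telescope from hip to ankle:
    ``(x_kh + x_ak) / (L1 + L2)`` with ``x_kh = L2 sin(hip + tilt)`` (knee
    anterior to hip) and ``x_ak = -L1 sin(ankle)`` (dorsiflexion carries
    the ankle posterior to the knee).  Positive values put the ankle
    anterior to the hip — a more anterior foot placement — and 0 means
    the ankle is directly below the hip.
    """
    x_kh = params.L[2] * np.sin(np.radians(state.hip + state.pelvic_tilt))
    x_ak = -params.L[1] * np.sin(np.radians(state.ankle))
    return float((x_kh + x_ak) / params.leg_length)


def pelvis_height(state: StateMSK, params: SegmentParams) -> float:
    """Vertical hip height above the ankle, normalized to leg length.

    ``(y_kh + y_ak) / (L1 + L2)`` with ``y_kh = L2 cos(hip + tilt)`` and
    ``y_ak = L1 cos(ankle)``; 1.0 is a fully extended leg.
    """
    y_kh = params.L[2] * np.cos(np.radians(state.hip + state.pelvic_tilt))
    y_ak = params.L[1] * np.cos(np.radians(state.ankle))
    return float((y_kh + y_ak) / params.leg_length)


def enumerate_states(
    spec: GridSpec | None = None,
    params: SegmentParams | None = None,
) -> pd.DataFrame:
    """Enumerate the constrained kinematic grid as a state table.

    The Cartesian product over ``theta1 x theta2 x theta3 x pelvic_tilt``
    (inclusive bounds, integer-degree arithmetic, theta_0 = 0) is filtered
    to states whose anatomical hip and lumbar angles fall inside the box
    constraints.  Rows are emitted in lexicographic axis order, one per
    state, with the MSK angles and — when ``params`` is given — the
    normalized foot-position and pelvis-height metrics.

    Raises :class:`EmptyGridError` if nothing survives the constraints.
    """
    spec = spec or GridSpec()
    rows = []
    for t1, t2, t3, tilt in itertools.product(
        spec.axis("theta1"), spec.axis("theta2"),
        spec.axis("theta3"), spec.axis("pelvic_tilt"),
    ):
        hip = t2 + t1 - tilt
        lumbar = hip + t3
        if spec.hip_range[0] <= hip <= spec.hip_range[1] and \
                spec.lumbar_range[0] <= lumbar <= spec.lumbar_range[1]:
            rows.append((0, t1, t2, t3, -t1, -t2, hip, lumbar, tilt))
    if not rows:
        raise EmptyGridError(
            f"no kinematic state satisfies hip in {spec.hip_range} and "
            f"lumbar in {spec.lumbar_range} over the grid {spec.ranges}"
        )
    df = pd.DataFrame(
        rows,
        columns=["theta0", "theta1", "theta2", "theta3",
                 "ankle", "knee", "hip", "lumbar", "pelvic_tilt"],
    )
    df.index.name = "state_id"
    if params is not None:
        attach_derived_metrics(df, params)
    return df


def attach_derived_metrics(grid: pd.DataFrame, params: SegmentParams) -> pd.DataFrame:
    """Add foot_position and pelvis_height columns to a state table in place."""
    hip_tilt = np.radians(grid["hip"] + grid["pelvic_tilt"])
    ankle = np.radians(grid["ankle"])
    leg = params.leg_length
    grid["foot_position"] = (
        params.L[2] * np.sin(hip_tilt) - params.L[1] * np.sin(ankle)
    ) / leg
    grid["pelvis_height"] = (
        params.L[2] * np.cos(hip_tilt) + params.L[1] * np.cos(ankle)
    ) / leg
    return grid


def msk_row_to_state(row) -> StateMSK:
    """Build a :class:`StateMSK` from a state-table row."""
    return StateMSK(
        ankle=float(row["ankle"]),
        knee=float(row["knee"]),
        hip=float(row["hip"]),
        lumbar=float(row["lumbar"]),
        pelvic_tilt=float(row["pelvic_tilt"]),
    )
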