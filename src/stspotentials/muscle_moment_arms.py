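"""Muscle moment arms [R]: geometric and tabulated providers, and the
mapping from anatomical joints onto the chain's generalized coordinates.

A moment arm is the tendon-excursion derivative ``-d(length)/d(angle)``.
Anatomical arms are defined about the MSK joints (ankle, knee, hip,
lumbar); the chain's generalized forces follow from the constant Jacobian
``D = d(theta_msk)/d(q)`` of the angle conversions:

    R_gen[j, m] = sum_c R_msk[c, m] * D[c, j]        (pelvic tilt fixed)

Attachment frames include the four chain links plus an anatomical
**pelvis** frame: its origin rides on the hip joint but its orientation
is set by the pelvic tilt alone (the pelvis posture is prescribed per
kinematic state, not slaved to the trunk link).  A hip muscle anchored on
the pelvis therefore has no lumbar moment arm, and its generalized column
reproduces the ``(r, r, r, 0)`` pattern of a pure hip torque.

Providers:

* :class:`GeometricMomentArmProvider` — straight-segment muscle paths
  attached to link/pelvis frames; arms computed analytically (or by
  central differences of path length for cross-checks).
* :class:`TabulatedMomentArmProvider` — multilinear interpolation of a
  long-format table of moment arms on a joint-angle grid, the ingestion
  route for arms exported from any musculoskeletal modeling tool.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .planar_model import N_LINKS, SegmentParams, State2D
from .state_space import StateMSK, from_msk

JOINTS = ("ankle", "knee", "hip", "lumbar")

#: Constant Jacobian D[c, j] = d(theta_msk_c)/d(theta_j), pelvic tilt fixed.
MSK_JACOBIAN = np.array(
    [
        [0.0, -1.0, 0.0, 0.0],   # ankle  = -theta_1
        [0.0, 0.0, -1.0, 0.0],   # knee   = -theta_2
        [1.0, 1.0, 1.0, 0.0],    # hip    = theta_0 + theta_1 + theta_2 - tilt
        [1.0, 1.0, 1.0, 1.0],    # lumbar = hip + theta_3
    ]
)


class MomentArmError(ValueError):
    """Raised for invalid muscle definitions or degenerate paths."""


class MomentArmCoverageError(MomentArmError):
    """Raised when a tabulated provider is queried outside its grid."""


#: Frame label for pelvis-bound attachment points.
PELVIS = "pelvis"


@dataclass(frozen=True)
class MuscleDef:
    """A muscle as an ordered straight-segment path over attachment frames.

    Each path point is ``(frame, (x, y))`` where ``frame`` is a link index
    0-3 or :data:`PELVIS`.  Local coordinates are meters in that frame:
    origin at the link's proximal joint (O, A, K or H; the pelvis frame
    sits on the hip), +y along the link toward its distal end (up, for the
    pelvis), +x anterior when the body stands upright with neutral tilt.
    ``spanned_joints`` lists the anatomical joints whose angles change the
    path length.
    """

    name: str
    spanned_joints: frozenset[str]
    path: tuple[tuple[int | str, tuple[float, float]], ...]
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise MomentArmError(f"muscle {self.name!r}: path needs >= 2 points")
        for link, _ in self.path:
            if link != PELVIS and link not in range(N_LINKS):
                raise MomentArmError(
                    f"muscle {self.name!r}: invalid attachment frame {link!r}"
                )
        unknown = set(self.spanned_joints) - set(JOINTS)
        if unknown:
            raise MomentArmError(
                f"muscle {self.name!r}: unknown joints {sorted(unknown)}"
            )
        if not self.group:
            object.__setattr__(self, "group", self.name)


@dataclass(frozen=True)
class MomentArmSet:
    """Anatomical (R_msk) and generalized (R_gen) moment arms, m/rad.

    ``R_msk`` is (4 anatomical joints x m muscles) in the order of
    :data:`JOINTS`; ``R_gen`` is (4 generalized coordinates x m muscles).
    """

    muscles: tuple[str, ...]
    groups: tuple[str, ...]
    R_msk: np.ndarray
    R_gen: np.ndarray


def map_to_generalized(R_msk: np.ndarray, pelvic_tilt_fixed: bool = True) -> np.ndarray:
    """Map anatomical moment arms onto the generalized coordinates.

    ``R_gen = D^T R_msk`` with the constant conversion Jacobian ``D``;
    pelvic tilt is held fixed (it is not a generalized coordinate of the
    chain, which is the only supported mode).
    """
    if not pelvic_tilt_fixed:
        raise NotImplementedError("pelvic tilt is not a generalized coordinate")
    R_msk = np.atleast_2d(np.asarray(R_msk, dtype=float))
    if R_msk.shape[0] != len(JOINTS):
        raise MomentArmError(
            f"R_msk must have {len(JOINTS)} joint rows, got {R_msk.shape}"
        )
    return MSK_JACOBIAN.T @ R_msk


# ---------------------------------------------------------------------------
# Geometric provider: straight-segment paths over link frames
# ---------------------------------------------------------------------------


def _frame_angles(state: State2D) -> np.ndarray:
    """Rotation angle of each link frame: s_i = theta_0 + ... + theta_i."""
    return state.cumulative()


def _joint_positions(state: State2D, params: SegmentParams) -> np.ndarray:
    s = _frame_angles(state)
    joints = np.zeros((N_LINKS, 2))
    direction = lambda a: np.array([-math.sin(a), math.cos(a)])
    joints[1] = params.L[0] * direction(s[0])
    joints[2] = joints[1] + params.L[1] * direction(s[1])
    joints[3] = joints[2] + params.L[2] * direction(s[2])
    return joints


def _rot(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s], [s, c]])


def path_point_world(
    link: int | str,
    local: Sequence[float],
    state: State2D,
    params: SegmentParams,
    pelvic_tilt: float = 0.0,
) -> np.ndarray:
    """World position of an attached point, m (``pelvic_tilt`` in radians).

    Pelvis-bound points ride on the hip joint and rotate with the tilt
    angle only (positive tilt = posterior = counterclockwise).
    """
    s = _frame_angles(state)
    joints = _joint_positions(state, params)
    u = np.asarray(local, dtype=float)
    if link == PELVIS:
        return joints[3] + _rot(pelvic_tilt) @ u
    return joints[link] + _rot(s[link]) @ u


def path_point_jacobian(
    link: int | str,
    local: Sequence[float],
    state: State2D,
    params: SegmentParams,
    pelvic_tilt: float = 0.0,
) -> np.ndarray:
    """2 x 4 Jacobian of an attached point's world position w.r.t. q.

    A pelvis-bound point translates with the hip but does not rotate with
    any generalized coordinate, so its columns are the hip-position
    Jacobian and its theta_3 column is zero.
    """
    s = _frame_angles(state)
    u = np.asarray(local, dtype=float)
    J = np.zeros((2, N_LINKS))
    if link == PELVIS:
        # hip position depends on theta_0..theta_2 through the leg links
        for c in range(3):
            col = np.zeros(2)
            for j in range(c, 3):
                col += params.L[j] * np.array([-math.cos(s[j]), -math.sin(s[j])])
            J[:, c] = col
        return J
    spin = _rot(s[link] + math.pi / 2) @ u
    for c in range(link + 1):
        # rotation of the link's own frame plus the swing of joints between
        col = spin.copy()
        for j in range(c, link):
            col += params.L[j] * np.array([-math.cos(s[j]), -math.sin(s[j])])
        J[:, c] = col
    return J


def musculotendon_length(
    muscle: MuscleDef,
    state: State2D,
    params: SegmentParams,
    pelvic_tilt: float = 0.0,
) -> float:
    """Total straight-segment path length, m (``pelvic_tilt`` radians)."""
    pts = [path_point_world(l, u, state, params, pelvic_tilt) for l, u in muscle.path]
    return float(sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])))


def generalized_moment_arms(
    muscle: MuscleDef,
    state: State2D,
    params: SegmentParams,
    pelvic_tilt: float = 0.0,
) -> np.ndarray:
    """Exact tendon-excursion column ``-d(length)/dq``, m/rad."""
    pts, jacs = [], []
    for link, local in muscle.path:
        pts.append(path_point_world(link, local, state, params, pelvic_tilt))
        jacs.append(path_point_jacobian(link, local, state, params, pelvic_tilt))
    grad = np.zeros(N_LINKS)
    for (p1, J1), (p2, J2) in zip(zip(pts, jacs), zip(pts[1:], jacs[1:])):
        seg = p2 - p1
        norm = np.linalg.norm(seg)
        if norm < 1e-12:
            raise MomentArmError(
                f"muscle {muscle.name!r}: degenerate zero-length path segment"
            )
        grad += (seg / norm) @ (J2 - J1)
    return -grad


def geometric_moment_arms(
    muscle: MuscleDef,
    state: StateMSK,
    params: SegmentParams,
    method: str = "analytic",
    fd_step_deg: float = 0.1,
) -> dict[str, float]:
    """Per-anatomical-joint moment arms ``-d(length)/d(theta_joint)``, m/rad.

    Moment arms are pure functions of the four anatomical angles.  On a
    foot-flat chain the five-angle parameterization is redundant (the tilt
    satisfies ``tilt = -(ankle + knee + hip)``), so the consistent tilt is
    derived from the declared joint angles here; a muscle length is
    rotation invariant, which makes the resulting arms independent of how
    the posture is embedded in the world.

    ``method='analytic'`` differentiates the straight-segment path exactly
    and decomposes through the inverse conversion Jacobian;
    ``method='fd'`` central-differences the path length in MSK angle space
    (default step 0.1 degree), the independent cross-check route.
    """

    def _embed(angles: dict[str, float]):
        tilt = -(angles["ankle"] + angles["knee"] + angles["hip"])
        q, _ = from_msk(StateMSK(**{**angles, "pelvic_tilt": tilt}))
        return q, math.radians(tilt)

    base = {k: v for k, v in state.as_dict().items() if k != "pelvic_tilt"}
    if method == "analytic":
        q, tilt_rad = _embed(base)
        g = generalized_moment_arms(muscle, q, params, tilt_rad)
        return dict(zip(JOINTS, np.linalg.solve(MSK_JACOBIAN.T, g)))
    if method != "fd":
        raise ValueError(f"unknown method {method!r}")
    h = fd_step_deg
    arms = {}
    for joint in JOINTS:
        lengths = []
        for sign in (+1, -1):
            angles = dict(base)
            angles[joint] += sign * h
            q, tilt_rad = _embed(angles)
            lengths.append(musculotendon_length(muscle, q, params, tilt_rad))
        arms[joint] = -(lengths[0] - lengths[1]) / (2 * math.radians(h))
    return arms


class GeometricMomentArmProvider:
    """Moment arms from bundled straight-segment muscle geometry."""

    def __init__(self, muscles: Sequence[MuscleDef], params: SegmentParams):
        if not muscles:
            raise MomentArmError("provider needs at least one muscle")
        self.muscle_defs = tuple(muscles)
        self.params = params

    @property
    def muscle_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.muscle_defs)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(m.group for m in self.muscle_defs)

    def moment_arms(self, state: StateMSK) -> MomentArmSet:
        R_msk = np.column_stack(
            [
                [geometric_moment_arms(m, state, self.params)[j] for j in JOINTS]
                for m in self.muscle_defs
            ]
        )
        return MomentArmSet(
            muscles=self.muscle_names,
            groups=self.groups,
            R_msk=R_msk,
            R_gen=map_to_generalized(R_msk),
        )

    __call__ = moment_arms


# ---------------------------------------------------------------------------
# Tabulated provider: multilinear interpolation over joint-angle grids
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ("muscle", "joint", "ankle", "knee", "hip", "lumbar", "moment_arm_m")


class TabulatedMomentArmProvider:
    """Moment arms interpolated from a long-format table.

    The table holds one row per (muscle, joint, angle-grid node) with the
    columns ``muscle, joint, ankle, knee, hip, lumbar, moment_arm_m``
    (angles degrees, arms meters).  For each (muscle, joint) pair, the
    angle columns with more than one distinct value form the interpolation
    axes — a full factorial grid over them is required — and the remaining
    angle columns are treated as irrelevant to that arm.  Queries outside
    the tabulated range raise :class:`MomentArmCoverageError` (no
    extrapolation).
    """

    def __init__(self, table: pd.DataFrame, groups: dict[str, str] | None = None):
        missing = set(TABLE_COLUMNS) - set(table.columns)
        if missing:
            raise MomentArmError(f"moment-arm table is missing columns {sorted(missing)}")
        self._interp: dict[tuple[str, str], tuple[tuple[str, ...], object]] = {}
        muscles = list(dict.fromkeys(table["muscle"]))
        group_col = table["group"] if "group" in table.columns else None
        self._groups = dict(groups or {})
        if group_col is not None and not self._groups:
            self._groups = dict(zip(table["muscle"], group_col))
        for (muscle, joint), grp in table.groupby(["muscle", "joint"], sort=False):
            axes = tuple(
                a for a in JOINTS if grp[a].nunique() > 1
            )
            if not axes:
                values = grp["moment_arm_m"].to_numpy()
                self._interp[(muscle, joint)] = ((), float(values[0]))
                continue
            coords = [np.sort(grp[a].unique()) for a in axes]
            expected = int(np.prod([len(c) for c in coords]))
            if len(grp) != expected:
                raise MomentArmError(
                    f"table for ({muscle}, {joint}) is not a full factorial grid "
                    f"over axes {axes}: {len(grp)} rows, expected {expected}"
                )
            pivot = grp.sort_values(list(axes))["moment_arm_m"].to_numpy()
            grid = pivot.reshape([len(c) for c in coords])
            self._interp[(muscle, joint)] = (
                axes,
                RegularGridInterpolator(coords, grid, method="linear", bounds_error=True),
            )
        self._muscles = tuple(muscles)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TabulatedMomentArmProvider":
        return cls(pd.read_csv(path, comment="#"))

    @property
    def muscle_names(self) -> tuple[str, ...]:
        return self._muscles

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self._groups.get(m, m) for m in self._muscles)

    def moment_arms(self, state: StateMSK) -> MomentArmSet:
        angles = state.as_dict()
        R_msk = np.zeros((len(JOINTS), len(self._muscles)))
        for col, muscle in enumerate(self._muscles):
            for row, joint in enumerate(JOINTS):
                entry = self._interp.get((muscle, joint))
                if entry is None:
                    continue
                axes, interp = entry
                if not axes:
                    R_msk[row, col] = interp
                    continue
                query = np.array([angles[a] for a in axes])
                try:
                    R_msk[row, col] = np.asarray(interp(query)).item()
                except ValueError as exc:
                    raise MomentArmCoverageError(
                        f"moment arm for ({muscle}, {joint}) not tabulated at "
                        f"state {angles}: {exc}"
                    ) from exc
        return MomentArmSet(
            muscles=self._muscles,
            groups=self.groups,
            R_msk=R_msk,
            R_gen=map_to_generalized(R_msk),
        )

    __call__ = moment_arms


# ---------------------------------------------------------------------------
# Muscle geometry JSON I/O
# ---------------------------------------------------------------------------


def muscles_to_json(muscles: Iterable[MuscleDef], path: str | Path) -> None:
    """Write muscle definitions to the geometry JSON schema."""
    payload = [
        {
            "name": m.name,
            "group": m.group,
            "spanned_joints": sorted(m.spanned_joints),
            "path": [
                {"frame": link, "point": [float(x), float(y)]}
                for link, (x, y) in m.path
            ],
        }
        for m in muscles
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def muscles_from_json(path: str | Path) -> tuple[MuscleDef, ...]:
    """Read muscle definitions from the geometry JSON schema."""
    payload = json.loads(Path(path).read_text())
    muscles = []
    for entry in payload:
        muscles.append(
            MuscleDef(
                name=entry["name"],
                group=entry.get("group", ""),
                spanned_joints=frozenset(entry["spanned_joints"]),
                path=tuple(
                    (
                        p["frame"] if p["frame"] == PELVIS else int(p["frame"]),
                        (float(p["point"][0]), float(p["point"][1])),
                    )
                    for p in entry["path"]
                ),
            )
        )
    return tuple(muscles)
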