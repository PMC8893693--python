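"""Four-link sagittal-plane model: parameters, coordinates, forward kinematics.

The body is modeled as a planar chain of four rigid links pinned at four
revolute joints:

* **Link 0** — the foot, a rigid triangle with vertices at the posterior
  calcaneus ``C``, the distal toe ``T`` and the ankle ``A``.  The world
  origin ``O`` lies on the ground line ``CT`` directly below ``A``; the
  segment ``OA`` is perpendicular to ``CT`` and rotates with the foot.
* **Link 1** — the shank, from the ankle ``A`` to the knee ``K``.
* **Link 2** — the thigh, from the knee ``K`` to the hip ``H``.
* **Link 3** — the lumped head-arms-torso (HAT, including the pelvis),
  from ``H`` to the HAT center of mass.

The chain is parameterized by four generalized coordinates ``theta_0`` ..
``theta_3`` (toe-pivot, ankle, knee, hip), measured counterclockwise, with
+X anterior and +Y superior.  The direction of link ``i`` (for i >= 1, and
of ``OA`` for i = 0) makes the angle ``theta_0 + ... + theta_i + 90 deg``
with the +X axis, so the reference posture ``theta = 0`` is an upright
stack of links.

Angles are radians internally; every file and CLI interface uses degrees.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

N_LINKS = 4

#: Acceleration of gravity used by the equations-of-motion oracle, m/s^2.
GRAVITY = 9.81


class ModelParameterError(ValueError):
    """Raised when segment parameters or a model file are invalid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentParams:
    """Inertial and geometric parameters of the four links.

    Parameters
    ----------
    m : per-link mass, kg.
    L : link lengths, m.  ``L[0]`` is the distance O->A, ``L[1]`` the shank
        length A->K, ``L[2]`` the thigh length K->H and ``L[3]`` a HAT
        reference length used only to bound ``r[3]``.
    r : distance from each link's proximal joint to its center of mass, m.
    I : moment of inertia of each link about its own COM, z-axis, kg m^2.
    theta_c : angle between CT and the vector from O to the link-0 COM, rad.
    foot_geometry : world positions (at ``theta_0 = 0``) of the foot
        triangle vertices ``C``, ``T`` and ``A``, m.
    """

    m: np.ndarray
    L: np.ndarray
    r: np.ndarray
    I: np.ndarray
    theta_c: float
    foot_geometry: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("m", "L", "r", "I"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_LINKS,):
                raise ModelParameterError(
                    f"{name} must have {N_LINKS} entries, got shape {arr.shape}"
                )
            object.__setattr__(self, name, arr)
        if np.any(self.m < 0):
            raise ModelParameterError(f"masses must be >= 0, got {self.m}")
        if np.any(self.L <= 0):
            raise ModelParameterError(f"lengths must be > 0, got {self.L}")
        if np.any(self.I < 0):
            raise ModelParameterError(f"inertias must be >= 0, got {self.I}")
        if np.any(self.r < 0) or np.any(self.r > self.L):
            raise ModelParameterError(
                f"COM offsets must satisfy 0 <= r_i <= L_i, got r={self.r}, L={self.L}"
            )
        if self.foot_geometry:
            self._validate_foot()

    def _validate_foot(self) -> None:
        try:
            c, t, a = (
                np.asarray(self.foot_geometry[k], dtype=float) for k in ("C", "T", "A")
            )
        except KeyError as exc:
            raise ModelParameterError(
                f"foot_geometry requires vertices C, T and A; missing {exc}"
            ) from exc
        for name, v in (("C", c), ("T", t), ("A", a)):
            if v.shape != (2,):
                raise ModelParameterError(f"foot vertex {name} must be 2D, got {v}")
        ct = t - c
        if abs(float(np.dot(ct, a))) > 1e-9 * (np.linalg.norm(ct) * np.linalg.norm(a) + 1e-12):
            raise ModelParameterError(
                "foot geometry invalid: OA must be perpendicular to CT "
                f"(C={c}, T={t}, A={a}; O is the origin)"
            )
        if not math.isclose(float(np.linalg.norm(a)), float(self.L[0]), rel_tol=1e-9, abs_tol=1e-9):
            raise ModelParameterError(
                f"|OA| = {np.linalg.norm(a):.6g} m does not match L_0 = {self.L[0]:.6g} m"
            )

    @property
    def total_mass(self) -> float:
        return float(self.m.sum())

    @property
    def leg_length(self) -> float:
        """Shank plus thigh length L_1 + L_2, m (normalization length)."""
        return float(self.L[1] + self.L[2])

    @classmethod
    def from_toml(cls, path: str | Path) -> "SegmentParams":
        """Load parameters from a TOML model file (strict schema).

        The file holds one ``[link0]`` .. ``[link3]`` table each with
        ``mass_kg``, ``length_m``, ``com_offset_m`` and ``inertia_kgm2``
        (``[link0]`` additionally ``theta_c_deg``), plus a ``[foot]`` table
        with 2-element vertices ``C``, ``T`` and ``A`` in meters.
        """
        path = Path(path)
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        m, L, r, inertia = (np.empty(N_LINKS) for _ in range(4))
        theta_c = 0.0
        for i in range(N_LINKS):
            key = f"link{i}"
            if key not in data:
                raise ModelParameterError(f"{path}: missing table [{key}]")
            table = data[key]
            for fieldname in ("mass_kg", "length_m", "com_offset_m", "inertia_kgm2"):
                if fieldname not in table:
                    raise ModelParameterError(
                        f"{path}: [{key}] is missing required key '{fieldname}'"
                    )
                if not isinstance(table[fieldname], (int, float)):
                    raise ModelParameterError(
                        f"{path}: [{key}].{fieldname} must be a number, "
                        f"got {table[fieldname]!r}"
                    )
            m[i] = table["mass_kg"]
            L[i] = table["length_m"]
            r[i] = table["com_offset_m"]
            inertia[i] = table["inertia_kgm2"]
            extras = set(table) - {
                "mass_kg", "length_m", "com_offset_m", "inertia_kgm2", "theta_c_deg",
            }
            if extras:
                raise ModelParameterError(
                    f"{path}: [{key}] has unknown keys {sorted(extras)}"
                )
            if i == 0:
                if "theta_c_deg" not in table:
                    raise ModelParameterError(
                        f"{path}: [link0] is missing required key 'theta_c_deg'"
                    )
                theta_c = math.radians(float(table["theta_c_deg"]))
        if "foot" not in data:
            raise ModelParameterError(f"{path}: missing table [foot]")
        foot = {}
        for name in ("C", "T", "A"):
            if name not in data["foot"]:
                raise ModelParameterError(f"{path}: [foot] is missing vertex '{name}'")
            foot[name] = np.asarray(data["foot"][name], dtype=float)
        return cls(m=m, L=L, r=r, I=inertia, theta_c=theta_c, foot_geometry=foot)

    def to_toml(self, path: str | Path) -> None:
        """Write the parameters back out in the model-file schema."""
        lines = []
        for i in range(N_LINKS):
            lines.append(f"[link{i}]")
            lines.append(f"mass_kg = {float(self.m[i])!r}")
            lines.append(f"length_m = {float(self.L[i])!r}")
            lines.append(f"com_offset_m = {float(self.r[i])!r}")
            lines.append(f"inertia_kgm2 = {float(self.I[i])!r}")
            if i == 0:
                lines.append(f"theta_c_deg = {math.degrees(self.theta_c)!r}")
            lines.append("")
        lines.append("[foot]")
        for name in ("C", "T", "A"):
            v = self.foot_geometry[name]
            lines.append(f"{name} = [{float(v[0])!r}, {float(v[1])!r}]")
        lines.append("")
        Path(path).write_text("\n".join(lines))


@dataclass(frozen=True)
class State2D:
    """Generalized coordinates of the chain, radians.

    ``theta[0]`` is the toe-pivot angle (0 for foot-flat states),
    ``theta[1]``..``theta[3]`` the ankle, knee and hip/trunk relative
    angles.
    """

    theta: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.theta, dtype=float)
        if arr.shape != (N_LINKS,):
            raise ModelParameterError(f"state needs {N_LINKS} angles, got {arr.shape}")
        object.__setattr__(self, "theta", arr)

    @classmethod
    def from_degrees(cls, theta_deg: Sequence[float]) -> "State2D":
        return cls(theta=np.radians(np.asarray(theta_deg, dtype=float)))

    @property
    def degrees(self) -> np.ndarray:
        return np.degrees(self.theta)

    def cumulative(self) -> np.ndarray:
        """Cumulative angle sums s_i = theta_0 + ... + theta_i, rad."""
        return np.cumsum(self.theta)


@dataclass(frozen=True)
class ForwardKinematics:
    """Joint, link-COM and whole-body-COM positions for one state, m."""

    joints: np.ndarray      # (4, 2): O, A, K, H
    link_coms: np.ndarray   # (4, 2)
    com: np.ndarray         # (2,) whole-body center of mass


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def lump_segments(
    segments: Sequence[tuple[float, Sequence[float], float]],
) -> tuple[float, np.ndarray, float]:
    """Combine rigid sub-segments into one (mass, COM, inertia) triple.

    Each entry is ``(mass_kg, com_xy_m, inertia_kgm2)`` with all COM
    positions in a common frame.  The lumped COM is the mass-weighted mean
    position and the lumped inertia follows the parallel-axis theorem:
    ``I = sum(I_k + m_k * d_k**2)`` with ``d_k`` the distance from segment
    COM to lumped COM.
    """
    if not segments:
        raise ModelParameterError("cannot lump an empty segment list")
    masses = np.array([float(s[0]) for s in segments])
    coms = np.array([np.asarray(s[1], dtype=float) for s in segments])
    inertias = np.array([float(s[2]) for s in segments])
    total = masses.sum()
    if total <= 0:
        raise ModelParameterError("lumped mass is zero: COM undefined")
    com = masses @ coms / total
    d2 = np.sum((coms - com) ** 2, axis=1)
    inertia = float(np.sum(inertias + masses * d2))
    return float(total), com, inertia


# Alias matching the anatomical use: HAT = torso + pelvis, foot = hindfoot bones.
lump_hat_and_foot = lump_segments


def _link_direction(angle: float | np.ndarray) -> np.ndarray:
    """Unit vector at ``angle + 90 deg`` from +X (the link-direction rule)."""
    return np.stack([-np.sin(angle), np.cos(angle)], axis=-1)


def forward_kinematics(state: State2D, params: SegmentParams) -> ForwardKinematics:
    """Positions of the joints O, A, K, H, the link COMs and the body COM.

    Link directions follow the cumulative-angle convention: link ``i``
    points along ``theta_0 + ... + theta_i + 90 deg`` counterclockwise from
    +X.  The link-0 COM sits at distance ``r_0`` from O along the angle
    ``theta_0 + theta_c`` (no 90 deg offset: ``theta_c`` is measured from
    the foot base CT itself).
    """
    s = state.cumulative()
    joints = np.zeros((N_LINKS, 2))
    joints[1] = params.L[0] * _link_direction(s[0])                  # A
    joints[2] = joints[1] + params.L[1] * _link_direction(s[1])      # K
    joints[3] = joints[2] + params.L[2] * _link_direction(s[2])      # H

    link_coms = np.zeros((N_LINKS, 2))
    th0c = state.theta[0] + params.theta_c
    link_coms[0] = params.r[0] * np.array([np.cos(th0c), np.sin(th0c)])
    for i in range(1, N_LINKS):
        link_coms[i] = joints[i] + params.r[i] * _link_direction(s[i])

    total = params.total_mass
    if total > 0:
        com = params.m @ link_coms / total
    else:
        com = np.full(2, np.nan)
    return ForwardKinematics(joints=joints, link_coms=link_coms, com=com)
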