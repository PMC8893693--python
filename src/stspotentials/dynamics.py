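"""Lagrangian dynamics of the chain: Jacobians, mass matrix, COM Jacobian.

The mass matrix is assembled from per-link Jacobians,

    M(q) = sum_i  m_i Jv_i^T Jv_i  +  I_i Jw_i^T Jw_i ,

where ``Jv_i`` (2 x 4) maps generalized velocities to the linear velocity
of link i's COM and ``Jw_i`` is the planar angular-velocity row
``(1, ..., 1, 0, ..., 0)`` with ones up to joint i (the x/y angular rows
vanish identically in plane motion, so only the z-row and the scalar
z-axis inertia are stored).

Gravity and Coriolis/centrifugal generalized forces are provided by
:func:`eom_terms` purely as a verification oracle — the potential operator
``M^{-1} R`` never uses them, since a per-Newton induced acceleration is
evaluated with gravity and velocity terms dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .planar_model import (
    GRAVITY,
    N_LINKS,
    ModelParameterError,
    SegmentParams,
    State2D,
    forward_kinematics,
)


@dataclass(frozen=True)
class EomTerms:
    """Gravity (G) and Coriolis/centrifugal (V) generalized forces, N m."""

    G: np.ndarray
    V: np.ndarray


def linear_jacobian(link_index: int, state: State2D, params: SegmentParams) -> np.ndarray:
    """2 x 4 Jacobian of the link-i COM position w.r.t. q, m/rad.

    Column c of the Jacobian is the partial derivative of (x, y) with
    respect to ``theta_c``; coordinates distal to the link get zero
    columns.  For i >= 1 the COM position is
    ``sum_j a_j * (cos(s_j + 90), sin(s_j + 90))`` with ``a_j = L_j`` for
    j < i and ``a_i = r_i``, so differentiating gives the truncated sums

        dx/dtheta_c = -sum_{j >= c} a_j cos(s_j),
        dy/dtheta_c = -sum_{j >= c} a_j sin(s_j),

    the pattern of the printed link-0 and link-3 matrices.  Link 0's COM
    sits at angle ``theta_0 + theta_c`` without the 90 deg offset.
    """
    if link_index not in range(N_LINKS):
        raise ValueError(f"link_index must be 0..{N_LINKS - 1}, got {link_index}")
    J = np.zeros((2, N_LINKS))
    if link_index == 0:
        th0c = state.theta[0] + params.theta_c
        J[0, 0] = -params.r[0] * np.sin(th0c)
        J[1, 0] = params.r[0] * np.cos(th0c)
        return J
    s = state.cumulative()[: link_index + 1]
    coeffs = np.append(params.L[:link_index], params.r[link_index])
    cx = coeffs * np.cos(s)
    sy = coeffs * np.sin(s)
    # column c collects every term with j >= c (reverse cumulative sum)
    J[0, : link_index + 1] = -(np.cumsum(cx[::-1])[::-1])
    J[1, : link_index + 1] = -(np.cumsum(sy[::-1])[::-1])
    return J


def angular_jacobian(link_index: int) -> np.ndarray:
    """Planar angular-velocity row of link i: entry j is 1 for j <= i."""
    if link_index not in range(N_LINKS):
        raise ValueError(f"link_index must be 0..{N_LINKS - 1}, got {link_index}")
    row = np.zeros(N_LINKS)
    row[: link_index + 1] = 1.0
    return row


def mass_matrix(state: State2D, params: SegmentParams) -> np.ndarray:
    """4 x 4 joint-space mass matrix, kg m^2.

    Exact evaluation of the Jacobian sum; symmetric by construction and
    positive definite whenever all masses and inertias are positive.
    Entries depend only on the relative angles ``theta_1..theta_3`` (a
    pinned chain's inertia is invariant to rigid rotation about the base).
    """
    M = np.zeros((N_LINKS, N_LINKS))
    for i in range(N_LINKS):
        Jv = linear_jacobian(i, state, params)
        w = angular_jacobian(i)
        M += params.m[i] * (Jv.T @ Jv) + params.I[i] * np.outer(w, w)
    return M


def com_jacobian(state: State2D, params: SegmentParams) -> np.ndarray:
    """2 x 4 Jacobian of the whole-body COM: mass-weighted mean of link Jacobians."""
    total = params.total_mass
    if total <= 0:
        raise ModelParameterError("COM Jacobian undefined for zero total mass")
    J = np.zeros((2, N_LINKS))
    for i in range(N_LINKS):
        J += params.m[i] * linear_jacobian(i, state, params)
    return J / total


# ---------------------------------------------------------------------------
# Full equations-of-motion oracle (verification only)
# ---------------------------------------------------------------------------


def gravity_vector(state: State2D, params: SegmentParams, g: float = GRAVITY) -> np.ndarray:
    """Generalized gravity force G = -d(PE)/dq, N m.

    PE = sum_i m_i g y_i, and dy_i/dq is the second row of the link
    Jacobian, so G_c = -g sum_i m_i Jv_i[1, c].
    """
    G = np.zeros(N_LINKS)
    for i in range(N_LINKS):
        G -= params.m[i] * g * linear_jacobian(i, state, params)[1]
    return G


def _coriolis_vector(state: State2D, qdot: np.ndarray, params: SegmentParams) -> np.ndarray:
    """Coriolis/centrifugal generalized force via Christoffel symbols of M.

    Built from central finite differences of the mass matrix
    (step 1e-6 rad), adequate for an oracle: V_k = -sum_{ij} c_{ijk}
    qd_i qd_j with c_{ijk} = (dM_kj/dq_i + dM_ki/dq_j - dM_ij/dq_k) / 2.
    """
    h = 1e-6
    dM = np.zeros((N_LINKS, N_LINKS, N_LINKS))  # dM[c] = dM/dq_c
    for c in range(N_LINKS):
        dq = np.zeros(N_LINKS)
        dq[c] = h
        Mp = mass_matrix(State2D(state.theta + dq), params)
        Mm = mass_matrix(State2D(state.theta - dq), params)
        dM[c] = (Mp - Mm) / (2 * h)
    V = np.zeros(N_LINKS)
    for k in range(N_LINKS):
        c_k = 0.5 * (dM[:, k, :] + dM[:, k, :].T - dM[k])  # c_{ijk} over (i, j)
        V[k] = -qdot @ c_k @ qdot
    return V


def eom_terms(
    state: State2D,
    velocities: np.ndarray,
    params: SegmentParams,
    g: float = GRAVITY,
) -> EomTerms:
    """Gravity and velocity generalized forces for the oracle EOM.

    The oracle integrates ``M(q) qdd = G(q) + V(q, qd) + Q``; internal pin
    forces do no virtual work in minimal coordinates, so no separate
    intersegmental term appears.
    """
    qdot = np.asarray(velocities, dtype=float)
    G = gravity_vector(state, params, g)
    if np.allclose(qdot, 0.0):
        V = np.zeros(N_LINKS)
    else:
        V = _coriolis_vector(state, qdot, params)
    return EomTerms(G=G, V=V)


def kinetic_energy(state: State2D, velocities: np.ndarray, params: SegmentParams) -> float:
    """Kinetic energy 0.5 qd^T M qd, J (oracle helper)."""
    qdot = np.asarray(velocities, dtype=float)
    return 0.5 * float(qdot @ mass_matrix(state, params) @ qdot)


def potential_energy(state: State2D, params: SegmentParams, g: float = GRAVITY) -> float:
    """Gravitational potential energy sum m_i g y_i, J (oracle helper)."""
    fk = forward_kinematics(state, params)
    return float(g * params.m @ fk.link_coms[:, 1])
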