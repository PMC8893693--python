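"""Mass matrix, Jacobians and the equations-of-motion oracle."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stspotentials.dynamics import (
    angular_jacobian,
    com_jacobian,
    eom_terms,
    kinetic_energy,
    linear_jacobian,
    mass_matrix,
    potential_energy,
)
from stspotentials.planar_model import ModelParameterError, SegmentParams, State2D, forward_kinematics
from stspotentials.synthetic_fixtures import random_state2d

FD_STEP = 1e-6


def fd_link_jacobian(link, state, params, h=FD_STEP):
    J = np.zeros((2, 4))
    for c in range(4):
        dq = np.zeros(4)
        dq[c] = h
        plus = forward_kinematics(State2D(state.theta + dq), params).link_coms[link]
        minus = forward_kinematics(State2D(state.theta - dq), params).link_coms[link]
        J[:, c] = (plus - minus) / (2 * h)
    return J


def energy_hessian(state, qd0, params, h=1e-4):
    """Hessian of kinetic energy w.r.t. generalized velocities (oracle)."""
    H = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            def ke(di, dj):
                qd = qd0.copy()
                qd[i] += di
                qd[j] += dj
                return kinetic_energy(state, qd, params)

            H[i, j] = (ke(h, h) - ke(h, -h) - ke(-h, h) + ke(-h, -h)) / (4 * h * h)
    return H


class TestLinearJacobian:
    def test_link0_matches_closed_form(self, params, rng):
        for _ in range(5):
            state = random_state2d(rng)
            th0c = state.theta[0] + params.theta_c
            expected = np.zeros((2, 4))
            expected[0, 0] = -params.r[0] * np.sin(th0c)
            expected[1, 0] = params.r[0] * np.cos(th0c)
            assert np.allclose(linear_jacobian(0, state, params), expected, atol=1e-15)

    def test_link3_matches_truncated_sums(self, params, rng):
        # entrywise form: column c is -(sum over terms j >= c) of a_j cos/sin(s_j)
        for _ in range(5):
            state = random_state2d(rng)
            s = np.cumsum(state.theta)
            a = np.array([params.L[0], params.L[1], params.L[2], params.r[3]])
            expected = np.zeros((2, 4))
            for c in range(4):
                expected[0, c] = -np.sum(a[c:] * np.cos(s[c:]))
                expected[1, c] = -np.sum(a[c:] * np.sin(s[c:]))
            assert np.allclose(linear_jacobian(3, state, params), expected, atol=1e-14)

    @pytest.mark.parametrize("link", [0, 1, 2, 3])
    def test_matches_finite_differences(self, link, params, rng):
        for _ in range(10):
            state = random_state2d(rng)
            J = linear_jacobian(link, state, params)
            assert np.abs(J - fd_link_jacobian(link, state, params)).max() < 1e-8

    def test_distal_columns_are_zero(self, params, rng):
        state = random_state2d(rng)
        for link in range(4):
            J = linear_jacobian(link, state, params)
            assert np.all(J[:, link + 1:] == 0.0)


@pytest.mark.parametrize(
    "link, expected",
    [
        (0, [1, 0, 0, 0]),
        (1, [1, 1, 0, 0]),
        (2, [1, 1, 1, 0]),
        (3, [1, 1, 1, 1]),
    ],
)
def test_angular_jacobian_chain_pattern(link, expected):
    assert np.array_equal(angular_jacobian(link), np.array(expected, dtype=float))


class TestMassMatrix:
    def test_zero_parameters_give_zero_matrix(self, params):
        empty = SegmentParams(m=[0] * 4, L=params.L, r=params.r, I=[0] * 4,
                              theta_c=params.theta_c)
        M = mass_matrix(State2D.from_degrees([0, -10, 80, -90]), empty)
        assert np.all(M == 0.0)

    def test_single_pendulum_closed_form(self, params):
        solo = SegmentParams(m=[params.m[0], 0, 0, 0], L=params.L, r=params.r,
                             I=[params.I[0], 0, 0, 0], theta_c=params.theta_c)
        M = mass_matrix(State2D.from_degrees([25, 0, 0, 0]), solo)
        expected = solo.I[0] + solo.m[0] * solo.r[0] ** 2
        assert M[0, 0] == pytest.approx(expected, rel=1e-14)
        M[0, 0] = 0.0
        assert np.all(M == 0.0)

    def test_equals_kinetic_energy_hessian(self, params, rng):
        for _ in range(10):
            state = random_state2d(rng)
            M = mass_matrix(state, params)
            H = energy_hessian(state, rng.standard_normal(4), params)
            assert np.abs(M - H).max() / np.abs(M).max() < 1e-6

    def test_symmetric_positive_definite(self, params, rng):
        for _ in range(20):
            M = mass_matrix(random_state2d(rng), params)
            assert np.abs(M - M.T).max() < 1e-12 * np.abs(M).max()
            assert np.linalg.eigvalsh(M).min() > 0

    def test_base_angle_invariance(self, params, rng):
        state = random_state2d(rng)
        shifted = State2D(state.theta + np.array([0.7, 0, 0, 0]))
        assert np.allclose(mass_matrix(state, params),
                           mass_matrix(shifted, params), atol=1e-12)

    def test_inertial_scaling_is_exact(self, params, rng):
        state = random_state2d(rng)
        scaled = SegmentParams(m=3 * params.m, L=params.L, r=params.r,
                               I=3 * params.I, theta_c=params.theta_c)
        assert np.allclose(3 * mass_matrix(state, params),
                           mass_matrix(state, scaled), rtol=1e-14)


class TestComJacobian:
    def test_single_massive_link_reduces_to_link_jacobian(self, params, rng):
        state = random_state2d(rng)
        solo = SegmentParams(m=[0, 0, 0, params.m[3]], L=params.L, r=params.r,
                             I=params.I, theta_c=params.theta_c)
        assert np.allclose(com_jacobian(state, solo),
                           linear_jacobian(3, state, solo), atol=1e-14)

    def test_predicts_com_velocity(self, params, rng):
        state = random_state2d(rng)
        qdot = rng.standard_normal(4)
        h = 1e-6
        plus = forward_kinematics(State2D(state.theta + h * qdot), params).com
        minus = forward_kinematics(State2D(state.theta - h * qdot), params).com
        fd = (plus - minus) / (2 * h)
        assert np.allclose(com_jacobian(state, params) @ qdot, fd, atol=1e-7)

    def test_last_column_excludes_proximal_links(self, params, rng):
        # only link 3 moves with theta_3, so column 3 carries its term alone
        state = random_state2d(rng)
        expected = params.m[3] * linear_jacobian(3, state, params)[:, 3] / params.total_mass
        assert np.allclose(com_jacobian(state, params)[:, 3], expected, atol=1e-14)

    def test_zero_mass_rejected(self, params):
        empty = SegmentParams(m=[0] * 4, L=params.L, r=params.r, I=params.I,
                              theta_c=params.theta_c)
        with pytest.raises(ModelParameterError):
            com_jacobian(State2D.from_degrees([0, 0, 0, 0]), empty)


class TestEomOracle:
    def test_velocity_terms_vanish_at_rest(self, params, rng):
        terms = eom_terms(random_state2d(rng), np.zeros(4), params)
        assert np.all(terms.V == 0.0)

    def test_gravity_vanishes_with_coms_on_vertical(self, params):
        # theta_c = 90 deg puts the foot COM on the OA line; the upright
        # posture then stacks every COM above O
        upright = SegmentParams(m=params.m, L=params.L, r=params.r, I=params.I,
                                theta_c=np.pi / 2)
        terms = eom_terms(State2D.from_degrees([0, 0, 0, 0]), np.zeros(4), upright)
        assert np.abs(terms.G).max() < 1e-10

    def test_energy_balance_along_trajectory(self, params, rng):
        state = random_state2d(rng)
        qd0 = 0.3 * rng.standard_normal(4)
        Q = np.array([1.0, -2.0, 0.5, 0.3])

        def rhs(t, y):
            q, qd = y[:4], y[4:]
            s = State2D(q)
            te = eom_terms(s, qd, params)
            return np.concatenate(
                [qd, np.linalg.solve(mass_matrix(s, params), te.G + te.V + Q)]
            )

        sol = solve_ivp(rhs, [0, 0.25], np.concatenate([state.theta, qd0]),
                        rtol=1e-10, atol=1e-12, dense_output=True)
        ts = np.linspace(0, 0.25, 2001)
        work = np.trapezoid(Q @ sol.sol(ts)[4:], ts)
        e0 = kinetic_energy(state, qd0, params) + potential_energy(state, params)
        qT, qdT = sol.y[:4, -1], sol.y[4:, -1]
        eT = kinetic_energy(State2D(qT), qdT, params) + potential_energy(State2D(qT), params)
        assert abs(eT - e0 - work) / max(abs(eT - e0), 1.0) < 1e-6
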