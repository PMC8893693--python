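"""Moment-arm providers and the anatomical-to-generalized mapping."""

import math

import numpy as np
import pandas as pd
import pytest

from stspotentials.muscle_moment_arms import (
    JOINTS,
    MSK_JACOBIAN,
    MomentArmCoverageError,
    MomentArmError,
    MuscleDef,
    PELVIS,
    TabulatedMomentArmProvider,
    generalized_moment_arms,
    geometric_moment_arms,
    map_to_generalized,
    muscles_from_json,
    muscles_to_json,
    musculotendon_length,
)
from stspotentials.state_space import StateMSK, from_msk
from stspotentials.synthetic_fixtures import random_states, tabulate_moment_arms

NEUTRAL = StateMSK(ankle=0, knee=-90, hip=90, lumbar=0, pelvic_tilt=0)


def fd_generalized_arms(muscle, msk, params, h=1e-7):
    """-d(length)/dq by central differences through forward kinematics."""
    q, tilt = from_msk(msk)
    tilt_rad = math.radians(tilt)
    grad = np.zeros(4)
    for c in range(4):
        dq = np.zeros(4)
        dq[c] = h
        lp = musculotendon_length(muscle, type(q)(q.theta + dq), params, tilt_rad)
        lm = musculotendon_length(muscle, type(q)(q.theta - dq), params, tilt_rad)
        grad[c] = (lp - lm) / (2 * h)
    return -grad


def states_to_msk(df):
    return [
        StateMSK(ankle=r.ankle, knee=r.knee, hip=r.hip, lumbar=r.lumbar,
                 pelvic_tilt=r.pelvic_tilt)
        for r in df.itertuples()
    ]


class TestGeometricArms:
    def test_single_link_muscle_has_zero_arms(self, params):
        muscle = MuscleDef(name="stub", spanned_joints=frozenset(),
                           path=((1, (0.0, 0.1)), (1, (0.02, 0.3))))
        arms = geometric_moment_arms(muscle, NEUTRAL, params)
        assert all(abs(v) < 1e-12 for v in arms.values())

    def test_pin_joint_perpendicular_distance(self, params):
        # a vertical cord passing distance d behind the ankle: the ankle
        # moment-arm magnitude is exactly d in the unrotated posture
        d = 0.037
        muscle = MuscleDef(name="cord", spanned_joints=frozenset({"ankle"}),
                           path=((0, (-d, 0.02)), (1, (-d, 0.05))))
        arms = geometric_moment_arms(
            muscle, StateMSK(ankle=0, knee=-90, hip=90, lumbar=0, pelvic_tilt=0),
            params,
        )
        assert abs(arms["ankle"]) == pytest.approx(d, rel=1e-9)
        assert arms["ankle"] < 0  # posterior cord plantarflexes

    def test_soleus_is_a_plausible_plantarflexor(self, params, muscles):
        soleus = next(m for m in muscles if m.name == "soleus")
        arm = geometric_moment_arms(soleus, NEUTRAL, params)["ankle"]
        assert -0.06 < arm < -0.02  # plantarflexion, 2-6 cm

    def test_degenerate_segment_rejected(self, params):
        muscle = MuscleDef(name="bad", spanned_joints=frozenset(),
                           path=((1, (0.0, 0.1)), (1, (0.0, 0.1))))
        with pytest.raises(MomentArmError, match="degenerate"):
            generalized_moment_arms(muscle, from_msk(NEUTRAL)[0], params)

    def test_analytic_agrees_with_msk_finite_differences(self, params, muscles):
        for msk in states_to_msk(random_states(5, seed=11)):
            for muscle in muscles:
                a = geometric_moment_arms(muscle, msk, params, method="analytic")
                b = geometric_moment_arms(muscle, msk, params, method="fd")
                for j in JOINTS:
                    # 0.1-degree central differences carry O(h^2) truncation
                    assert a[j] == pytest.approx(b[j], abs=5e-7)

    def test_unspanned_joints_have_zero_arms(self, params, muscles):
        for msk in states_to_msk(random_states(3, seed=5)):
            for muscle in muscles:
                arms = geometric_moment_arms(muscle, msk, params)
                for j in JOINTS:
                    if j not in muscle.spanned_joints:
                        assert abs(arms[j]) < 1e-10


class TestMapping:
    def test_ankle_only_column(self):
        r = 0.04
        R_gen = map_to_generalized(np.array([[r], [0.0], [0.0], [0.0]]))
        assert np.allclose(R_gen[:, 0], [0.0, -r, 0.0, 0.0])

    def test_hip_only_column(self):
        r = 0.06
        R_gen = map_to_generalized(np.array([[0.0], [0.0], [r], [0.0]]))
        assert np.allclose(R_gen[:, 0], [r, r, r, 0.0])

    def test_chain_rule_consistency_with_path_length(self, params, muscles, provider):
        # the strongest internal check: mapping the anatomical arms must
        # reproduce the exact tendon-excursion column -dL/dq
        for msk in states_to_msk(random_states(20, seed=3)):
            arms = provider.moment_arms(msk)
            for col, muscle in enumerate(muscles):
                fd = fd_generalized_arms(muscle, msk, params)
                assert np.abs(arms.R_gen[:, col] - fd).max() < 1e-6

    def test_sign_flip_round_trip(self, provider):
        # flipping a joint's positive direction flips the R_msk row; the
        # consistently flipped conversion Jacobian restores R_gen
        arms = provider.moment_arms(NEUTRAL)
        for row in range(4):
            flip = np.ones((4, 1))
            flip[row] = -1.0
            D_flipped = MSK_JACOBIAN * flip
            assert np.allclose(D_flipped.T @ (arms.R_msk * flip), arms.R_gen)

    def test_shape_validation(self):
        with pytest.raises(MomentArmError):
            map_to_generalized(np.zeros((3, 2)))


@pytest.fixture(scope="module")
def table(params, muscles):
    return tabulate_moment_arms(muscles, params)


class TestTabulatedProvider:

    def test_exact_at_grid_nodes(self, table, params, muscles, provider):
        tab = TabulatedMomentArmProvider(table)
        node = StateMSK(ankle=10, knee=-90, hip=90, lumbar=0, pelvic_tilt=0)
        geo = provider.moment_arms(node)
        interp = tab.moment_arms(node)
        order = [interp.muscles.index(m) for m in geo.muscles]
        assert np.allclose(interp.R_msk[:, order], geo.R_msk, atol=1e-12)

    def test_constant_table_is_constant_everywhere(self):
        rows = []
        for ankle in (0, 20, 40):
            rows.append({"muscle": "m", "joint": "ankle", "ankle": ankle,
                         "knee": -90, "hip": 90, "lumbar": 0, "moment_arm_m": -0.04})
        tab = TabulatedMomentArmProvider(pd.DataFrame(rows))
        for ankle in (0.0, 7.5, 33.0):
            arms = tab.moment_arms(StateMSK(ankle=ankle, knee=-90, hip=90,
                                            lumbar=0, pelvic_tilt=0))
            assert arms.R_msk[0, 0] == pytest.approx(-0.04)

    def test_linear_table_interpolates_exactly(self):
        rows = []
        for ankle in range(0, 41, 5):
            rows.append({"muscle": "m", "joint": "ankle", "ankle": ankle,
                         "knee": -90, "hip": 90, "lumbar": 0,
                         "moment_arm_m": 0.01 + 0.0004 * ankle})
        tab = TabulatedMomentArmProvider(pd.DataFrame(rows))
        for ankle in (2.5, 17.5, 38.75):
            arms = tab.moment_arms(StateMSK(ankle=ankle, knee=-90, hip=90,
                                            lumbar=0, pelvic_tilt=0))
            assert arms.R_msk[0, 0] == pytest.approx(0.01 + 0.0004 * ankle, abs=1e-12)

    def test_out_of_range_query_raises(self, table):
        tab = TabulatedMomentArmProvider(table)
        with pytest.raises(MomentArmCoverageError):
            tab.moment_arms(StateMSK(ankle=60, knee=-90, hip=90, lumbar=0,
                                     pelvic_tilt=0))

    def test_non_factorial_grid_rejected(self):
        rows = [
            {"muscle": "m", "joint": "ankle", "ankle": a, "knee": k,
             "hip": 90, "lumbar": 0, "moment_arm_m": 0.01}
            for a, k in [(0, -90), (10, -90), (10, -80)]
        ]
        with pytest.raises(MomentArmError, match="factorial"):
            TabulatedMomentArmProvider(pd.DataFrame(rows))


class TestGeometryIO:
    def test_json_round_trip(self, muscles, tmp_path):
        path = tmp_path / "muscles.json"
        muscles_to_json(muscles, path)
        loaded = muscles_from_json(path)
        assert loaded == tuple(muscles)
        assert any(link == PELVIS for m in loaded for link, _ in m.path)
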