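"""Synthetic default inputs: anthropometry, muscle geometry, tables, states.

Everything needed to run the tool ships as code here — no download, no
external modeling software.

**Anthropometry (synthetic fixture).**  Per-link values are built from
standard gait-model segment proportions: a torso+pelvis lump forms the
HAT link and talus+calcaneus+toes form the foot (both by the parallel-
axis lumping rule).  Both legs are folded into each leg link (masses and
inertias doubled) so the single sagittal chain carries the whole body.
The result is normalized so the totals match the generic-model printed
constraints exactly: total mass 75.2 kg and leg length L1 + L2 = 0.826 m.
Per-link values are otherwise NOT from the source musculoskeletal model
and are marked as fixture approximations.

**Muscle geometry (synthetic fixture).**  Eight actuators — gluteus
maximus, biceps femoris (long head), rectus femoris, vasti, the medial
and lateral gastrocnemius heads, soleus and tibialis anterior — as
straight-segment paths with original, anatomically plausible attachment
coordinates in link frames (origin at the proximal joint, +y toward the
distal joint, +x anterior in upright standing).  They reproduce each
muscle's sagittal-plane actions (sign and centimeter-scale magnitude of
its moment arms), not any specific model's values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .muscle_moment_arms import (
    JOINTS,
    PELVIS,
    MuscleDef,
    TabulatedMomentArmProvider,
    geometric_moment_arms,
    muscles_to_json,
)
from .planar_model import SegmentParams, State2D, lump_segments
from .state_space import DEFAULT_RANGES, MSK_RANGES, GridSpec, StateMSK, enumerate_states

#: Printed generic-model totals the fixture is constrained to.
TOTAL_MASS_KG = 75.2
LEG_LENGTH_M = 0.826

_L1 = 0.430   # shank length A->K, m
_L2 = 0.396   # thigh length K->H, m  (L1 + L2 = 0.826)
_L0 = 0.080   # ankle height |OA|, m
_L3 = 0.600   # HAT reference length, m (bounds r_3 only)

# Sub-segment tables (mass kg, COM m, I_zz kg m^2), standard-proportion
# approximations.  Foot COMs are in the foot frame (origin O under the
# ankle); HAT COMs are relative to the hip, +y up in upright standing.
_FOOT_SEGMENTS = [
    (0.100, (0.000, 0.065), 0.0010),   # talus
    (1.250, (0.045, 0.030), 0.0041),   # calcaneus
    (0.217, (0.160, 0.010), 0.0001),   # toes
]
_HAT_SEGMENTS = [
    (34.237, (0.000, 0.350), 1.4745),  # torso + head + arms
    (11.777, (-0.070, 0.000), 0.0871), # pelvis
]
_SHANK = (3.7075, 0.245, 0.0504)       # mass, r from ankle, I_zz (per leg)
_THIGH = (9.3014, 0.225, 0.1339)       # mass, r from knee, I_zz (per leg)

FOOT_VERTICES = {"C": (-0.050, 0.0), "T": (0.180, 0.0), "A": (0.0, _L0)}


def default_segment_params() -> SegmentParams:
    """The bundled 4-link anthropometry (synthetic fixture, see module doc)."""
    m_foot, com_foot, i_foot = lump_segments(_FOOT_SEGMENTS)
    m_hat, com_hat, i_hat = lump_segments(_HAT_SEGMENTS)
    # both legs folded into the single chain
    m = np.array([2 * m_foot, 2 * _SHANK[0], 2 * _THIGH[0], m_hat])
    inertia = np.array([2 * i_foot, 2 * _SHANK[2], 2 * _THIGH[2], i_hat])
    scale = TOTAL_MASS_KG / m.sum()
    r3 = float(np.linalg.norm(com_hat))  # link 3 is defined along hip->HAT COM
    return SegmentParams(
        m=m * scale,
        L=np.array([_L0, _L1, _L2, _L3]),
        r=np.array([float(np.linalg.norm(com_foot)), _SHANK[1], _THIGH[1], r3]),
        I=inertia * scale,
        theta_c=float(np.arctan2(com_foot[1], com_foot[0])),
        foot_geometry={k: np.asarray(v, dtype=float) for k, v in FOOT_VERTICES.items()},
    )


# Attachment coordinates, m, in link-local frames (see module docstring).
# Shank points measure y from the ANKLE (knee at y = L1 = 0.430); thigh
# points from the KNEE (hip at y = L2 = 0.396); HAT points from the hip.
#
# Straight-segment paths collapse onto a joint center at deep flexion, so
# each joint carries pulley-style via points (retro-malleolar groove and
# dorsal retinaculum at the ankle, patellar mechanism and posterior
# condyles at the knee, ischial wrap at the hip), the standard device of
# straight-line muscle models to keep moment arms anatomically sized over
# the whole motion range.
def default_muscles() -> tuple[MuscleDef, ...]:
    """The bundled eight-actuator muscle set (synthetic fixture)."""
    patella = (2, (0.048, 0.000))           # patellar via, front of distal femur
    below_knee_ant = (1, (0.045, 0.425))    # tibial tuberosity region
    retro_malleolar = (1, (-0.045, 0.030))  # Achilles groove, behind the ankle
    heel = (0, (-0.050, 0.015))             # Achilles insertion on the heel
    return (
        MuscleDef(
            name="gluteus_maximus",
            spanned_joints=frozenset({"hip"}),
            # the wrap via sits at the posterior pelvic rim near hip level,
            # reproducing the published extension-arm profile: largest
            # (~6 cm) near hip extension, shrinking with deep flexion
            path=(
                (PELVIS, (-0.085, 0.050)),  # sacrum / posterior ilium
                (PELVIS, (-0.080, -0.010)), # posterior pelvic wrap via
                (2, (-0.035, 0.330)),       # gluteal tuberosity of the femur
            ),
        ),
        MuscleDef(
            name="biceps_femoris_lh",
            spanned_joints=frozenset({"hip", "knee"}),
            # hip arm grows with flexion (ischial origin swings away from
            # the joint); knee arm stays in the 1.5-3 cm band reported for
            # deep knee flexion
            path=(
                (PELVIS, (-0.045, -0.085)), # ischial tuberosity (wrap point)
                (2, (-0.034, 0.130)),       # posterior femoral shaft via
                (1, (-0.030, 0.405)),       # fibular head
            ),
        ),
        MuscleDef(
            name="rectus_femoris",
            spanned_joints=frozenset({"hip", "knee"}),
            # proximal anchor raised to the ASIS/iliac region: a straight
            # chord from the AIIS loses its flexion arm past ~80 deg of hip
            # flexion, where the real muscle wraps the femoral head
            path=(
                (PELVIS, (0.035, 0.075)),   # anterior ilium (ASIS region)
                (2, (0.012, 0.358)),        # femoral-head wrap via
                patella,
                below_knee_ant,
            ),
        ),
        MuscleDef(
            name="vasti",
            spanned_joints=frozenset({"knee"}),
            path=((2, (0.035, 0.200)), patella, below_knee_ant),
        ),
        MuscleDef(
            name="gastrocnemius_medialis",
            group="gastrocnemius",
            spanned_joints=frozenset({"knee", "ankle"}),
            path=((2, (-0.014, 0.020)), (1, (-0.016, 0.405)), retro_malleolar, heel),
        ),
        MuscleDef(
            name="gastrocnemius_lateralis",
            group="gastrocnemius",
            spanned_joints=frozenset({"knee", "ankle"}),
            path=((2, (-0.015, 0.019)), (1, (-0.017, 0.404)), retro_malleolar, heel),
        ),
        MuscleDef(
            name="soleus",
            spanned_joints=frozenset({"ankle"}),
            path=((1, (-0.030, 0.300)), retro_malleolar, heel),
        ),
        MuscleDef(
            name="tibialis_anterior",
            spanned_joints=frozenset({"ankle"}),
            path=(
                (1, (0.025, 0.280)),        # anterior tibial shaft
                (1, (0.030, 0.038)),        # dorsal retinaculum via
                (0, (0.058, 0.045)),        # medial cuneiform / first metatarsal
            ),
        ),
    )


#: Anatomical actions each fixture muscle must reproduce: joint -> sign of
#: its moment arm in the MSK convention (+dorsiflexion, +knee extension,
#: +hip flexion).
EXPECTED_ARM_SIGNS: dict[str, dict[str, int]] = {
    "gluteus_maximus": {"hip": -1},
    "biceps_femoris_lh": {"hip": -1, "knee": -1},
    "rectus_femoris": {"hip": +1, "knee": +1},
    "vasti": {"knee": +1},
    "gastrocnemius_medialis": {"knee": -1, "ankle": -1},
    "gastrocnemius_lateralis": {"knee": -1, "ankle": -1},
    "soleus": {"ankle": -1},
    "tibialis_anterior": {"ankle": +1},
}


def tabulate_moment_arms(
    muscles=None,
    params: SegmentParams | None = None,
    increment: int = 5,
) -> pd.DataFrame:
    """Long-format moment-arm table over the anatomical ranges.

    For each muscle, its spanned joints' angles are swept over the
    anatomical ranges at ``increment`` degrees (full factorial) while the
    unspanned angles sit at the initial-posture reference (ankle 0, knee
    -90, hip 90, lumbar 0) — a straight-segment arm does not depend on
    joints outside the spanned set, so the restricted grid is exact.
    """
    muscles = muscles or default_muscles()
    params = params or default_segment_params()
    reference = {"ankle": 0.0, "knee": -90.0, "hip": 90.0, "lumbar": 0.0}
    records = []
    for muscle in muscles:
        axes = [j for j in JOINTS if j in muscle.spanned_joints]
        grids = [
            np.arange(MSK_RANGES[a][0], MSK_RANGES[a][1] + 1, increment, dtype=float)
            for a in axes
        ]
        mesh = np.meshgrid(*grids, indexing="ij") if axes else []
        combos = (
            np.stack([g.ravel() for g in mesh], axis=1)
            if axes
            else np.zeros((1, 0))
        )
        for combo in combos:
            angles = dict(reference)
            angles.update(zip(axes, combo))
            state = StateMSK(**angles, pelvic_tilt=0.0)
            arms = geometric_moment_arms(muscle, state, params)
            for joint in JOINTS:
                if joint not in muscle.spanned_joints:
                    continue
                records.append(
                    {
                        "muscle": muscle.name,
                        "group": muscle.group,
                        "joint": joint,
                        **angles,
                        "moment_arm_m": arms[joint],
                    }
                )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of a generated fixture set plus the seed it was built with."""

    model_file: Path
    muscle_file: Path
    moment_arm_file: Path
    seed: int


def generate_bundle(outdir: str | Path, seed: int = 0) -> FixtureBundle:
    """Write the full fixture set (model TOML, muscle JSON, moment-arm CSV).

    The bundle is deterministic: regeneration with the same seed is
    byte-identical (the fixtures themselves carry no randomness; the seed
    is recorded for provenance of downstream random-state draws).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = default_segment_params()
    muscles = default_muscles()

    model_file = outdir / "model.toml"
    params.to_toml(model_file)

    muscle_file = outdir / "muscles.json"
    muscles_to_json(muscles, muscle_file)

    moment_arm_file = outdir / "moment_arms.csv"
    table = tabulate_moment_arms(muscles, params)
    with open(moment_arm_file, "w") as fh:
        fh.write("# moment arms, meters; angles, degrees (MSK convention)\n")
        table.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")
    return FixtureBundle(
        model_file=model_file,
        muscle_file=muscle_file,
        moment_arm_file=moment_arm_file,
        seed=seed,
    )


def tabulated_provider_from_bundle(bundle: FixtureBundle) -> TabulatedMomentArmProvider:
    return TabulatedMomentArmProvider.from_csv(bundle.moment_arm_file)


def random_states(
    n: int,
    seed: int,
    within_grid: bool = True,
    spec: GridSpec | None = None,
) -> pd.DataFrame:
    """Random kinematic states for property tests.

    ``within_grid=True`` samples uniformly from the enumerated
    (constraint-respecting) grid; otherwise angles are drawn continuously
    and uniformly over the 2D-model boxes and the pelvic-tilt range,
    without the anatomical constraints.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if within_grid:
        grid = enumerate_states(spec)
        idx = rng.integers(0, len(grid), size=n)
        out = grid.iloc[idx].reset_index(drop=True)
        out.index.name = "state_id"
        return out
    ranges = (spec.ranges if spec else DEFAULT_RANGES)
    cols = {}
    for name in ("theta1", "theta2", "theta3", "pelvic_tilt"):
        lo, hi = ranges[name]
        cols[name] = rng.uniform(lo, hi, size=n)
    df = pd.DataFrame(cols)
    df.insert(0, "theta0", 0.0)
    df["ankle"] = -df["theta1"]
    df["knee"] = -df["theta2"]
    df["hip"] = df["theta2"] + df["theta1"] - df["pelvic_tilt"]
    df["lumbar"] = df["hip"] + df["theta3"]
    df.index.name = "state_id"
    return df


def random_state2d(rng: np.random.Generator) -> State2D:
    """One unconstrained continuous chain state (radians), for oracles."""
    lo = np.array([-0.5, -0.8, 1.2, -2.7])
    hi = np.array([0.5, 0.1, 1.8, -1.0])
    return State2D(rng.uniform(lo, hi))
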