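"""Per-muscle potentials: induced COM acceleration per Newton of force.

For a static kinematic state the induced joint accelerations of a unit
muscle force are the columns of ``M(q)^{-1} R(q)`` (gravity, velocity and
intersegmental terms drop out of a per-Newton contribution), and the
whole-body COM acceleration follows from the COM Jacobian:

    (progression, support) = J_com(q) @ M(q)^{-1} R(q)[:, muscle]

Support is the vertical (+Y, superior) component and progression the
anteroposterior (+X, anterior) component, in m/(N s^2).  Potentials scale
inversely with body inertia (doubling every mass and inertia halves every
potential) and linearly in the moment arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .dynamics import com_jacobian, mass_matrix
from .muscle_moment_arms import MomentArmCoverageError, MomentArmSet
from .planar_model import SegmentParams
from .state_space import StateMSK, from_msk, msk_row_to_state

#: Reject states whose mass matrix is this ill-conditioned.
CONDITION_LIMIT = 1e12


class SingularMassMatrixError(np.linalg.LinAlgError):
    """Raised when M is singular or numerically ill-conditioned."""


@dataclass(frozen=True)
class PotentialResult:
    """Per-muscle potentials at one kinematic state.

    ``qdd_potential`` holds the induced joint accelerations per Newton
    (4 x m, rad/(N s^2)); ``support_potential`` / ``progression_potential``
    the vertical / anteroposterior COM components (m, in m/(N s^2)).
    """

    muscles: tuple[str, ...]
    groups: tuple[str, ...]
    qdd_potential: np.ndarray
    support_potential: np.ndarray
    progression_potential: np.ndarray


def joint_potentials(M: np.ndarray, R_gen: np.ndarray) -> np.ndarray:
    """Solve ``M P = R_gen`` column-wise, rad/(N s^2).

    Uses a symmetric-positive-definite factorization rather than explicit
    inversion; a singular or ill-conditioned M (condition number above
    ``CONDITION_LIMIT``) raises :class:`SingularMassMatrixError`.
    """
    M = np.asarray(M, dtype=float)
    R_gen = np.atleast_2d(np.asarray(R_gen, dtype=float))
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise SingularMassMatrixError(
            f"mass matrix is singular or ill-conditioned (cond = {cond:.3e})"
        )
    try:
        factor = cho_factor(M, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by cond
        raise SingularMassMatrixError(f"mass matrix not positive definite: {exc}")
    return cho_solve(factor, R_gen)


def task_potentials(P_joint: np.ndarray, J_com: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project joint potentials to COM task space.

    Returns ``(progression, support)`` per muscle: the X (anterior +) and
    Y (superior +) rows of ``J_com @ P_joint``, m/(N s^2).
    """
    task = np.asarray(J_com, dtype=float) @ np.atleast_2d(P_joint)
    return task[0], task[1]


def compute_potentials(
    state: StateMSK,
    provider,
    params: SegmentParams,
) -> PotentialResult:
    """Full potential computation for one anatomical state."""
    q, _ = from_msk(state)
    arms: MomentArmSet = provider.moment_arms(state)
    P = joint_potentials(mass_matrix(q, params), arms.R_gen)
    progression, support = task_potentials(P, com_jacobian(q, params))
    return PotentialResult(
        muscles=arms.muscles,
        groups=arms.groups,
        qdd_potential=P,
        support_potential=support,
        progression_potential=progression,
    )


def sweep(
    states: pd.DataFrame,
    provider,
    params: SegmentParams,
) -> pd.DataFrame:
    """Potentials for every state of a state table.

    Returns one row per (state, muscle) with the state's angles and
    derived metrics carried along; provider coverage gaps are re-raised
    with the offending state attached.
    """
    state_cols = [c for c in states.columns]
    records = []
    for state_id, row in states.iterrows():
        msk = msk_row_to_state(row)
        try:
            res = compute_potentials(msk, provider, params)
        except MomentArmCoverageError as exc:
            raise MomentArmCoverageError(
                f"state {state_id} not covered by the moment-arm provider: {exc}"
            ) from exc
        base = {"state_id": state_id, **{c: row[c] for c in state_cols}}
        for i, muscle in enumerate(res.muscles):
            records.append(
                {
                    **base,
                    "muscle": muscle,
                    "group": res.groups[i],
                    "support_potential": res.support_potential[i],
                    "progression_potential": res.progression_potential[i],
                }
            )
    return pd.DataFrame.from_records(records)


def group_mean_potentials(sweep_table: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Collapse multi-head actuators (e.g. the two gastrocnemius heads)
    to one row per (state, group).

    ``how`` is ``'mean'`` (default: grouped muscles report the mean of
    their component potentials) or ``'sum'``.
    """
    if how not in ("mean", "sum"):
        raise ValueError(f"how must be 'mean' or 'sum', got {how!r}")
    value_cols = ["support_potential", "progression_potential"]
    keys = [c for c in sweep_table.columns if c not in value_cols + ["muscle"]]
    agg = sweep_table.groupby(["state_id", "group"], sort=False).agg(
        {**{c: "first" for c in keys if c not in ("state_id", "group")},
         **{c: how for c in value_cols}}
    )
    return agg.reset_index().rename(columns={"group": "muscle"})


def aggregate_by(
    sweep_table: pd.DataFrame,
    parameter: str,
    task: str = "support",
    decimals: int = 6,
) -> pd.DataFrame:
    """Mean and SD of a potential per unique value of a kinematic parameter.

    States are grouped by the exact grid value for angle parameters and by
    the value rounded to ``decimals`` for the continuous derived metrics
    (foot position, pelvis height).  ``task`` is ``'support'`` or
    ``'progression'``.
    """
    col = f"{task}_potential"
    if col not in sweep_table.columns:
        raise ValueError(f"unknown task {task!r}")
    if parameter not in sweep_table.columns:
        raise ValueError(f"unknown kinematic parameter {parameter!r}")
    key = sweep_table[parameter]
    if parameter in ("foot_position", "pelvis_height"):
        key = key.round(decimals)
    out = (
        sweep_table.assign(**{parameter: key})
        .groupby(["muscle", parameter], sort=True)[col]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return out.rename(columns={"mean": f"{col}_mean", "std": f"{col}_sd", "count": "n_states"})
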