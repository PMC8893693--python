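"""Correlation analysis of potentials versus kinematic modifications.

Muscle potentials across the enumerated state space are not normally
distributed, so both variables receive a rank-based inverse normal
transform (Blom scores by default) before a Pearson correlation.
Correlation strength is categorized on the magnitude of r:

    very weak |r| < 0.2, weak < 0.4, moderate < 0.6, strong < 0.8,
    very strong >= 0.8,

with the sign reported separately.  The full analysis correlates each
analyzed muscle's support and progression potentials against four
kinematic modifiers: foot position, pelvis height, lumbar flexion and
pelvic tilt.  Lumbar *flexion* is the negated lumbar state angle (the
state tables store positive = extension), so positive correlations mean
the potential grows with a more flexed lumbar spine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Blom rank-score offset: Phi^-1((rank - c) / (n + 1 - 2c)) with c = 3/8.
BLOM_OFFSET = 0.375

ALPHA = 0.05

CATEGORY_BOUNDS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
)

#: The seven analyzed muscles (gastrocnemius = mean of its two heads).
ANALYZED_MUSCLES = (
    "gluteus_maximus",
    "biceps_femoris_lh",
    "rectus_femoris",
    "vasti",
    "gastrocnemius",
    "soleus",
    "tibialis_anterior",
)

TASKS = ("support", "progression")
MODIFIERS = ("foot_position", "pelvis_height", "lumbar_flexion", "pelvic_tilt")


class DegenerateDataError(ValueError):
    """Raised for inputs whose ranks or variance are undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    muscle: str
    task: str
    modifier: str
    r: float
    p: float
    category: str


def rank_inverse_normal(x, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal transform with average-rank ties.

    ``value_i = Phi^-1((rank_i - offset) / (n + 1 - 2*offset))``; the
    default offset 3/8 gives Blom scores, for which the transform of the
    middle of three distinct values is exactly 0.  Invariant under any
    strictly increasing transform of ``x``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise DegenerateDataError(f"need a 1-D vector with n >= 3, got shape {x.shape}")
    if np.all(x == x[0]):
        raise DegenerateDataError("all input values identical: ranks undefined")
    ranks = sps.rankdata(x, method="average")
    n = x.size
    return sps.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateDataError("pearson needs two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("pearson undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def categorize(r: float) -> str:
    """Strength label from |r| (sign reported separately)."""
    mag = abs(float(r))
    if mag > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    for bound, label in CATEGORY_BOUNDS:
        if mag < bound:
            return label
    return "very strong"


def lilliefors_pvalue(x) -> float:
    """Lilliefors normality-test p-value (optional report field).

    The pipeline applies the rank-INT regardless; this mirrors the
    normality pre-check for reporting only.
    """
    from statsmodels.stats.diagnostic import lilliefors

    return float(lilliefors(np.asarray(x, dtype=float), dist="norm")[1])


def correlation_analysis(
    sweep_table: pd.DataFrame,
    muscles=ANALYZED_MUSCLES,
    with_normality: bool = False,
) -> pd.DataFrame:
    """Full correlation report: muscles x (support, progression) x modifiers.

    ``sweep_table`` is a per-(state, muscle) potential table (grouped
    actuators already collapsed, see
    :func:`~stspotentials.potential_engine.group_mean_potentials`) whose
    state columns include ``foot_position``, ``pelvis_height``, ``lumbar``
    and ``pelvic_tilt``.  Both variables are rank-INT transformed before
    the Pearson correlation.  Degenerate (constant) columns are flagged in
    the ``note`` column with NaN statistics rather than aborting the
    report.
    """
    rows = []
    for muscle in muscles:
        sub = sweep_table[sweep_table["muscle"] == muscle]
        if sub.empty:
            raise DegenerateDataError(f"no sweep rows for muscle {muscle!r}")
        modifier_values = {
            "foot_position": sub["foot_position"].to_numpy(),
            "pelvis_height": sub["pelvis_height"].to_numpy(),
            "lumbar_flexion": -sub["lumbar"].to_numpy(),
            "pelvic_tilt": sub["pelvic_tilt"].to_numpy(),
        }
        for task in TASKS:
            pot = sub[f"{task}_potential"].to_numpy()
            for modifier in MODIFIERS:
                row = {"muscle": muscle, "task": task, "modifier": modifier,
                       "r": np.nan, "p": np.nan, "category": "", "note": ""}
                try:
                    tx = rank_inverse_normal(modifier_values[modifier])
                    ty = rank_inverse_normal(pot)
                    r, p = pearson(tx, ty)
                    row.update(r=r, p=p, category=categorize(r))
                except DegenerateDataError as exc:
                    row["note"] = str(exc)
                if with_normality and not row["note"]:
                    row["potential_lilliefors_p"] = lilliefors_pvalue(pot)
                rows.append(row)
    return pd.DataFrame(rows)
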