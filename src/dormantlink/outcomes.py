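"""Outcome derivation: exam points, standardised scores, binary attainment.

The primary outcome is the GCSE mathematics grade at age 16 expressed as
a standard-deviation score within each trial; secondary outcomes are the
corresponding English score, age-11 (key stage 2) scores, attainment of
five or more GCSEs at grade C or above including mathematics and
English, and ever receiving special-educational-needs support.
Letter grades map to the 8-point scale (A* = 8 ... G = 1, U = 0).

Internal standardisation uses the sample mean and SD (n-1 denominator)
over the linked, outcome-complete, surviving participants of the trial,
both arms pooled; external standardisation uses the per-year national
reference distribution instead and serves as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthcohort import GCSE_SUBJECTS, GRADES_ASC, OutcomeModel, Register, TrialCohort

__all__ = [
    "GCSE_POINTS",
    "ScoreScale",
    "DegenerateScaleError",
    "grade_to_points",
    "standardise_internal",
    "standardise_external",
    "derive_binary_outcomes",
    "build_analysis_dataset",
    "CONTINUOUS_OUTCOMES",
    "BINARY_OUTCOMES",
]

GCSE_POINTS = {g: float(i) for i, g in enumerate(GRADES_ASC)}  # U=0 .. A*=8

CONTINUOUS_OUTCOMES = ("sd_maths16", "sd_english16", "sd_maths11", "sd_english11")
BINARY_OUTCOMES = ("five_plus_gcse_c", "sen_ever")


class DegenerateScaleError(ValueError):
    """Raised when a standardisation scale has no spread."""


@dataclass
class ScoreScale:
    """Points map plus per-year national reference for one exam subject."""

    subject: str
    stage: str  # age16_gcse | age11_ks2
    points: dict = field(default_factory=lambda: dict(GCSE_POINTS))
    national: dict = field(default_factory=dict)  # year -> (mean, sd)

    def __post_init__(self) -> None:
        ordered = [self.points[g] for g in GRADES_ASC if g in self.points]
        if any(b <= a for a, b in zip(ordered, ordered[1:])):
            raise ValueError("points map must be strictly monotone in grade order")
        for year, (_, sd) in self.national.items():
            if sd <= 0:
                raise ValueError(f"national SD for {year} must be positive")

    @classmethod
    def from_outcome_model(
        cls,
        model: OutcomeModel,
        subject: str = "maths",
        years: range = range(2004, 2020),
    ) -> "ScoreScale":
        national = {y: model.national_reference(y) for y in years}
        return cls(subject=subject, stage="age16_gcse", national=national)


def grade_to_points(grades: pd.Series | np.ndarray) -> np.ndarray:
    """Letter grades to points; unknown/missing grades map to NaN."""
    return np.array(
        [GCSE_POINTS.get(g, np.nan) if isinstance(g, str) else np.nan for g in np.asarray(grades, dtype=object)]
    )


def standardise_internal(points: pd.Series | np.ndarray) -> np.ndarray:
    """Z-scores against the sample distribution of the given points.

    Uses the sample SD (n-1 denominator) over non-missing values; the
    result has mean 0 and sample SD 1 exactly. Raises
    :class:`DegenerateScaleError` for fewer than two distinct non-missing
    values.
    """
    x = np.asarray(points, dtype=float)
    obs = x[~np.isnan(x)]
    if len(obs) < 2:
        raise DegenerateScaleError("need at least 2 non-missing scores")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise DegenerateScaleError("constant scores cannot be standardised")
    return (x - obs.mean()) / sd


def standardise_external(
    points: pd.Series | np.ndarray,
    scale: ScoreScale,
    years: pd.Series | np.ndarray,
) -> np.ndarray:
    """Z-scores against the per-year national reference distribution."""
    x = np.asarray(points, dtype=float)
    out = np.full(len(x), np.nan)
    for i, (v, y) in enumerate(zip(x, np.asarray(years))):
        if np.isnan(v):
            continue
        if pd.isna(y) or int(y) not in scale.national:
            raise KeyError(f"no national reference for exam year {y}")
        mean, sd = scale.national[int(y)]
        out[i] = (v - mean) / sd
    return out


def derive_binary_outcomes(
    gcse_grades: dict, sen_history=None
) -> tuple[float, float]:
    """(five_plus_gcse_c, sen_ever) from a subject->grade map and SEN flags.

    The attainment indicator is 1 iff at least five subjects are at grade
    C or above AND both mathematics and English are among them; it is
    missing (NaN) when no grades are present. ``sen_ever`` is 1 iff any
    recorded year flags support.
    """
    grades = {s: g for s, g in (gcse_grades or {}).items() if isinstance(g, str)}
    if not grades:
        five = np.nan
    else:
        at_c = {s for s, g in grades.items() if GCSE_POINTS.get(g, 0) >= GCSE_POINTS["C"]}
        five = float(len(at_c) >= 5 and "maths" in at_c and "english" in at_c)
    if sen_history is None:
        sen = np.nan
    else:
        flags = [f for f in np.asarray(sen_history, dtype=float).ravel() if not np.isnan(f)]
        sen = float(any(f == 1 for f in flags)) if flags else np.nan
    return five, sen


def build_analysis_dataset(
    cohort: TrialCohort,
    register: Register,
    decisions: pd.DataFrame,
    outcome_model: OutcomeModel | None = None,
) -> pd.DataFrame:
    """Intention-to-treat analysis table: one row per randomised participant.

    Unlinked participants are retained with missing outcomes; deceased
    participants are retained with a death flag (they are excluded from
    imputation and analysis downstream). Continuous outcomes are
    internally standardised within trial on the linked, non-missing,
    surviving participants (arms pooled) before any imputation; the
    externally standardised GCSE mathematics score is attached alongside.
    """
    model = outcome_model or OutcomeModel()
    parts = cohort.participants.copy()
    df = parts.merge(
        decisions[["participant_id", "pupil_id", "status"]], on="participant_id", how="left"
    )
    df["linked"] = (df["status"] == "linked").astype(int)

    pupil_cols = (
        ["pupil_id", "ks2_maths", "ks2_english", "ks2_year", "gcse_year", "sen_ever"]
        + [f"gcse_{s}" for s in GCSE_SUBJECTS]
    )
    df = df.merge(register.pupils[pupil_cols], on="pupil_id", how="left")

    df["pts_maths16"] = grade_to_points(df["gcse_maths"])
    df["pts_english16"] = grade_to_points(df["gcse_english"])

    raw_map = {
        "sd_maths16": "pts_maths16",
        "sd_english16": "pts_english16",
        "sd_maths11": "ks2_maths",
        "sd_english11": "ks2_english",
    }
    for out_col in CONTINUOUS_OUTCOMES:
        df[out_col] = np.nan
    for trial_id, idx in df.groupby("trial_id").groups.items():
        alive = df.loc[idx, "death"] == 0
        for out_col, raw_col in raw_map.items():
            vals = pd.to_numeric(df.loc[idx, raw_col], errors="coerce")
            vals[~alive] = np.nan
            if vals.notna().sum() < 2 or vals.std(ddof=1) == 0:
                continue  # outcome unavailable for this trial (e.g. too young)
            df.loc[idx, out_col] = standardise_internal(vals)

    scale = ScoreScale.from_outcome_model(model, "maths")
    has_pts = df["pts_maths16"].notna()
    df["ext_maths16"] = np.nan
    if has_pts.any():
        df.loc[has_pts, "ext_maths16"] = standardise_external(
            df.loc[has_pts, "pts_maths16"], scale, df.loc[has_pts, "gcse_year"]
        )

    grade_cols = {s: f"gcse_{s}" for s in GCSE_SUBJECTS}
    fives = []
    for row in df.itertuples(index=False):
        grades = {
            s: getattr(row, c) for s, c in grade_cols.items()
        }
        five, _ = derive_binary_outcomes(grades, None)
        fives.append(five)
    df["five_plus_gcse_c"] = fives
    df.loc[df["death"] == 1, ["five_plus_gcse_c", "sen_ever"]] = np.nan
    df["arm_modified"] = (df["arm"] == "modified").astype(int)

    keep = [
        "participant_id", "trial_id", "arm", "arm_modified", "centre",
        "sex", "birth_weight", "gestational_age", "maternal_age",
        "maternal_smoking", "maternal_degree", "death", "twin_group",
        "linked", "status", "pupil_id", "gcse_year",
        "pts_maths16", "pts_english16",
        *CONTINUOUS_OUTCOMES, "ext_maths16", *BINARY_OUTCOMES,
    ]
    return df[keep]
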