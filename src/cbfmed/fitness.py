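"""Subject-level physiological indices: estimated cardiorespiratory fitness
(eCRF) and pulse pressure.

eCRF is a non-exercise regression proxy for VO2max (in metabolic equivalents)
built from gender, age, body-mass index, resting heart rate and a self-reported
physical-activity score:

    eCRF = 2.77*gender - 0.10*age - 0.17*BMI - 0.03*RHR + activity + 18.07

The gender coding (which sex receives the +2.77 offset) is a configuration
choice; the default codes female = 1.  All downstream analyses residualize
gender, so results do not depend on this choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ECRF_COEFFS",
    "compute_ecrf",
    "pulse_pressure",
    "add_fitness_columns",
]

#: Coefficients of the eCRF estimating equation.
ECRF_COEFFS = {
    "gender": 2.77,
    "age": -0.10,
    "bmi": -0.17,
    "resting_heart_rate": -0.03,
    "activity_score": 1.0,
    "intercept": 18.07,
}


def compute_ecrf(gender_code, age, bmi, resting_heart_rate, activity_score,
                 *, strict: bool = False):
    """Evaluate the eCRF estimating equation (vectorized).

    Parameters
    ----------
    gender_code : 0/1 indicator (1 receives the +2.77 offset; default
        convention: female = 1).
    age : years.
    bmi : kg/m^2.
    resting_heart_rate : beats/min.
    activity_score : self-reported activity scale value; accepted as a real
        number (synthetic cohorts back-solve it continuously).
    strict : when True, reject physiologically impossible inputs
        (age < 0, bmi <= 0, resting_heart_rate <= 0).

    Returns
    -------
    eCRF in metabolic equivalents, same shape as the broadcast inputs.
    """
    gender_code = np.asarray(gender_code, dtype=float)
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    rhr = np.asarray(resting_heart_rate, dtype=float)
    activity = np.asarray(activity_score, dtype=float)
    if strict:
        if np.any(age < 0):
            raise ValueError("age must be >= 0")
        if np.any(bmi <= 0):
            raise ValueError("bmi must be > 0")
        if np.any(rhr <= 0):
            raise ValueError("resting_heart_rate must be > 0")
    out = (
        ECRF_COEFFS["gender"] * gender_code
        + ECRF_COEFFS["age"] * age
        + ECRF_COEFFS["bmi"] * bmi
        + ECRF_COEFFS["resting_heart_rate"] * rhr
        + ECRF_COEFFS["activity_score"] * activity
        + ECRF_COEFFS["intercept"]
    )
    return out if out.ndim else float(out)


def solve_activity_score(ecrf, gender_code, age, bmi, resting_heart_rate):
    """Invert the eCRF equation for the activity score.

    Used by the synthetic cohort generator so that the generated covariates
    reproduce a target eCRF exactly.  The result is continuous, not
    restricted to the ordinal categories of the original self-report scale.
    """
    base = compute_ecrf(gender_code, age, bmi, resting_heart_rate, 0.0)
    return np.asarray(ecrf, dtype=float) - base


def pulse_pressure(systolic, diastolic):
    """Pulse pressure = systolic minus diastolic blood pressure (mmHg)."""
    systolic = np.asarray(systolic, dtype=float)
    diastolic = np.asarray(diastolic, dtype=float)
    if np.any(systolic < diastolic):
        raise ValueError("systolic pressure must be >= diastolic pressure")
    out = systolic - diastolic
    return out if out.ndim else float(out)


def add_fitness_columns(cohort: pd.DataFrame, *, strict: bool = False) -> pd.DataFrame:
    """Return a copy of a cohort table with ``ecrf`` and ``pulse_pressure`` added.

    Expects columns ``gender_code, age, bmi, resting_heart_rate,
    activity_score, systolic_bp, diastolic_bp``.
    """
    required = ["gender_code", "age", "bmi", "resting_heart_rate",
                "activity_score", "systolic_bp", "diastolic_bp"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    out = cohort.copy()
    out["ecrf"] = compute_ecrf(
        cohort["gender_code"], cohort["age"], cohort["bmi"],
        cohort["resting_heart_rate"], cohort["activity_score"], strict=strict,
    )
    out["pulse_pressure"] = pulse_pressure(cohort["systolic_bp"], cohort["diastolic_bp"])
    return out
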