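"""Participant anthropometrics and covariate encoding.

Holds the per-child record (age, sex, height, mass) used both by the
weight-status classifications and as regression covariates.  Reference
percentile tables (BMI-for-age 95th percentile; waist-circumference
cuts) are external CSV inputs with columns
``(age_years, sex, cut_name, value)`` — published growth charts are not
embedded.  Lookup is nearest-age within sex; no LMS interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Participant",
    "compute_bmi",
    "classify_bmi_status",
    "classify_wc_status",
    "encode_covariates",
    "load_reference_table",
]

SEX_CODES = {"female": 0, "male": 1}


@dataclass(frozen=True)
class Participant:
    id: str
    age: float
    sex: str
    height: float  # m
    mass: float  # kg
    waist_circumference: float | None = None  # cm

    def __post_init__(self):
        if self.height <= 0 or self.mass <= 0:
            raise ValueError("height and mass must be positive")
        if not 0 < self.age < 18:
            raise ValueError("age must be in (0, 18) years")
        if self.sex not in SEX_CODES:
            raise ValueError("sex must be 'male' or 'female'")

    @property
    def bmi(self) -> float:
        return compute_bmi(self.mass, self.height)


def compute_bmi(mass: float, height: float) -> float:
    """Body mass index: kilograms per square of the height in metres."""
    if mass <= 0 or height <= 0:
        raise ValueError("mass and height must be positive")
    return mass / height**2


def load_reference_table(path) -> pd.DataFrame:
    """Read a percentile reference CSV (age_years, sex, cut_name, value)."""
    table = pd.read_csv(path)
    missing = {"age_years", "sex", "cut_name", "value"} - set(table.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    return table


def _lookup_cut(reference_table: pd.DataFrame, age: float, sex: str, cut_name: str) -> float:
    rows = reference_table[
        (reference_table["sex"] == sex) & (reference_table["cut_name"] == cut_name)
    ]
    if rows.empty:
        raise KeyError(f"no reference rows for sex={sex!r}, cut={cut_name!r}")
    idx = (rows["age_years"] - age).abs().idxmin()
    return float(rows.loc[idx, "value"])


def classify_bmi_status(bmi: float, age: float, sex: str, reference_table: pd.DataFrame) -> str:
    """Weight status from a BMI-for-age chart: overweight at or above the 95th percentile."""
    cut = _lookup_cut(reference_table, age, sex, "bmi_p95")
    return "overweight" if bmi >= cut else "normal"


def classify_wc_status(wc: float, age: float, sex: str, reference_table: pd.DataFrame) -> str:
    """Waist-circumference status against lower/upper cuts for (age, sex).

    Below the lower cut is underweight, between the cuts normal, at or
    above the upper cut overweight/obese.
    """
    lower = _lookup_cut(reference_table, age, sex, "wc_lower")
    upper = _lookup_cut(reference_table, age, sex, "wc_upper")
    if not lower < upper:
        raise ValueError(f"waist cuts out of order for age={age}, sex={sex}: {lower} >= {upper}")
    if wc < lower:
        return "underweight"
    if wc < upper:
        return "normal"
    return "overweight/obese"


def encode_covariates(participants) -> pd.DataFrame:
    """Build the (age, bmi, sex) covariate matrix for the regressions.

    Sex is coded female=0 / male=1; age and BMI pass through on their
    native scales.  Accepts a DataFrame with columns
    (id, age, sex, height, mass) — or an explicit ``bmi`` column — or an
    iterable of :class:`Participant`.
    """
    if not isinstance(participants, pd.DataFrame):
        participants = pd.DataFrame(
            [
                {"id": p.id, "age": p.age, "sex": p.sex, "height": p.height, "mass": p.mass}
                for p in participants
            ]
        )
    frame = participants.copy()
    if "bmi" not in frame.columns:
        for col in ("height", "mass"):
            if col not in frame.columns:
                raise ValueError(f"cannot derive bmi: missing column {col!r}")
        frame["bmi"] = frame["mass"] / frame["height"] ** 2
    for col in ("id", "age", "sex", "bmi"):
        if col not in frame.columns:
            raise ValueError(f"missing participant column {col!r}")
        bad = frame[frame[col].isna()]
        if not bad.empty:
            raise ValueError(
                f"missing {col!r} for participant(s): {bad['id'].tolist() if col != 'id' else bad.index.tolist()}"
            )
    unknown = set(frame["sex"]) - set(SEX_CODES)
    if unknown:
        raise ValueError(f"unrecognised sex values: {sorted(unknown)}")
    out = pd.DataFrame(
        {
            "age": frame["age"].astype(float).to_numpy(),
            "bmi": frame["bmi"].astype(float).to_numpy(),
            "sex": frame["sex"].map(SEX_CODES).astype(float).to_numpy(),
        },
        index=pd.Index(frame["id"], name="participant_id"),
    )
    return out
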