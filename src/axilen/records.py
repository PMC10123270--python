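"""Per-eye biometry records, the cohort table schema, and CSV round-trip I/O.

A cohort is carried in memory as a :class:`pandas.DataFrame` with one row
per eye and a fixed column schema (see :data:`REQUIRED_COLUMNS` /
:data:`DERIVED_COLUMNS`).  :class:`BiometryRecord` is the validated
single-record view used where per-record guarantees matter.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Eye",
    "Gender",
    "BiometryRecord",
    "PHYSIOLOGICAL_GUARDS",
    "REQUIRED_COLUMNS",
    "DERIVED_COLUMNS",
    "ALL_COLUMNS",
    "CohortParseError",
    "guard_mask",
    "empty_cohort",
    "read_cohort",
    "write_cohort",
]


class Eye(str, enum.Enum):
    OD = "OD"  # right eye
    OS = "OS"  # left eye


class Gender(str, enum.Enum):
    female = "female"
    male = "male"


#: Physiological plausibility bounds (open intervals) for measured variables.
PHYSIOLOGICAL_GUARDS: dict[str, tuple[float, float]] = {
    "cr_mm": (5.0, 12.0),
    "al_mm": (15.0, 40.0),
    "ssi": (0.2, 2.5),
    "cct_um": (300.0, 800.0),
}

REQUIRED_COLUMNS = [
    "subject_id",
    "eye",
    "age",
    "gender",
    "ser_d",
    "ssi",
    "cct_um",
    "cr_mm",
    "al_mm",
]

DERIVED_COLUMNS = ["al_morgan_mm", "al_emmetropia_mm", "delta_al_mm"]

ALL_COLUMNS = REQUIRED_COLUMNS + DERIVED_COLUMNS


class BiometryRecord(BaseModel):
    """One eye's measured variables plus the derived model quantities.

    Measured fields must satisfy the physiological guards; the derived
    fields (``al_morgan``, ``al_emmetropia``, ``delta_al``) are optional
    on input and, when both ``al`` and ``al_emmetropia`` are present,
    ``delta_al`` must equal their difference.
    """

    model_config = ConfigDict(extra="forbid")

    subject_id: str
    eye: Eye
    age: float = Field(gt=0, lt=120)
    gender: Gender
    ser_d: float
    ssi: float = Field(gt=PHYSIOLOGICAL_GUARDS["ssi"][0], lt=PHYSIOLOGICAL_GUARDS["ssi"][1])
    cct_um: float = Field(gt=PHYSIOLOGICAL_GUARDS["cct_um"][0], lt=PHYSIOLOGICAL_GUARDS["cct_um"][1])
    cr_mm: float = Field(gt=PHYSIOLOGICAL_GUARDS["cr_mm"][0], lt=PHYSIOLOGICAL_GUARDS["cr_mm"][1])
    al_mm: float = Field(gt=PHYSIOLOGICAL_GUARDS["al_mm"][0], lt=PHYSIOLOGICAL_GUARDS["al_mm"][1])
    al_morgan_mm: Optional[float] = None
    al_emmetropia_mm: Optional[float] = None
    delta_al_mm: Optional[float] = None

    @model_validator(mode="after")
    def _delta_consistent(self) -> "BiometryRecord":
        if self.delta_al_mm is not None and self.al_emmetropia_mm is not None:
            if abs(self.delta_al_mm - (self.al_mm - self.al_emmetropia_mm)) > 1e-6:
                raise ValueError(
                    f"delta_al_mm={self.delta_al_mm} inconsistent with "
                    f"al_mm - al_emmetropia_mm = {self.al_mm - self.al_emmetropia_mm}"
                )
        return self


class CohortParseError(ValueError):
    """Raised when a cohort file has malformed rows or a broken schema."""


def guard_mask(table: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows satisfying every physiological guard."""
    ok = pd.Series(True, index=table.index)
    for col, (lo, hi) in PHYSIOLOGICAL_GUARDS.items():
        if col in table.columns:
            vals = table[col].astype(float)
            ok &= np.isfinite(vals) & (vals > lo) & (vals < hi)
    return ok


def empty_cohort(include_derived: bool = True) -> pd.DataFrame:
    """An empty cohort table with the full column schema."""
    cols = ALL_COLUMNS if include_derived else REQUIRED_COLUMNS
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    for c in ("subject_id", "eye", "gender"):
        df[c] = df[c].astype(object)
    return df[cols]


_VALID_EYES = {e.value for e in Eye}
_VALID_GENDERS = {g.value for g in Gender}


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort CSV, validating schema and categorical codes.

    Values pass through verbatim (no sign or unit munging).  Raises
    :class:`CohortParseError` naming the offending line for missing
    columns, unparseable numerics, or unknown eye/gender codes.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except Exception as exc:  # malformed CSV structure
        raise CohortParseError(f"{path}: cannot parse cohort file: {exc}") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing required columns {missing}")

    numeric_cols = [c for c in df.columns if c not in ("subject_id", "eye", "gender")]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise CohortParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = coerced

    if len(df):
        bad_eye = ~df["eye"].isin(_VALID_EYES)
        if bad_eye.any():
            line = int(bad_eye.idxmax()) + 2
            raise CohortParseError(
                f"{path}: unknown eye code {df['eye'][bad_eye.idxmax()]!r} at line {line}"
            )
        bad_gender = ~df["gender"].isin(_VALID_GENDERS)
        if bad_gender.any():
            line = int(bad_gender.idxmax()) + 2
            raise CohortParseError(
                f"{path}: unknown gender code {df['gender'][bad_gender.idxmax()]!r} "
                f"at line {line}"
            )
        null_req = df[REQUIRED_COLUMNS].isna().any(axis=1)
        if null_req.any():
            line = int(null_req.idxmax()) + 2
            raise CohortParseError(f"{path}: missing required value at line {line}")

    ordered = [c for c in ALL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def write_cohort(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a cohort table as UTF-8 CSV with full float precision.

    The write -> :func:`read_cohort` round trip is lossless to <= 1e-9 on
    numeric fields (floats are serialised with repr precision).
    """
    path = Path(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns {missing}")
    ordered = [c for c in ALL_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in ordered]
    table[ordered + extra].to_csv(path, index=False, float_format="%.12g", encoding="utf-8")
    return path
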