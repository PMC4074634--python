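"""ACR-1982 criterion-count case classification.

Chart review records eleven boolean classification criteria per patient;
a patient is confirmed as a true SLE case when at least four of the eleven
are satisfied.  This module defines the criteria vocabulary, the scalar
record type, the counting/classification rules (scalar and vectorised),
and the verification-table reader.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

from .claims_core import DataError, SchemaError

#: The eleven ACR-1982 classification criteria, in canonical column order.
CRITERIA = (
    "malar_rash",
    "discoid_rash",
    "photosensitivity",
    "oral_ulcer",
    "arthritis",
    "serositis",
    "renal_disorder",
    "hematologic_disorder",
    "neurologic_disorder",
    "immunologic_disorder",
    "fana_positive",
)

#: Minimum number of satisfied criteria for a confirmed SLE classification.
SLE_CRITERION_THRESHOLD = 4


@dataclass(frozen=True)
class CriteriaRecord:
    """The eleven criterion flags for one chart-reviewed patient."""

    malar_rash: bool = False
    discoid_rash: bool = False
    photosensitivity: bool = False
    oral_ulcer: bool = False
    arthritis: bool = False
    serositis: bool = False
    renal_disorder: bool = False
    hematologic_disorder: bool = False
    neurologic_disorder: bool = False
    immunologic_disorder: bool = False
    fana_positive: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not isinstance(value, bool):
                raise DataError(f"criterion {f.name} must be strictly boolean, got {value!r}")

    @classmethod
    def from_flags(cls, flags) -> "CriteriaRecord":
        """Build a record from any mapping or 11-vector in canonical order."""
        if hasattr(flags, "keys"):
            return cls(**{name: bool(flags[name]) for name in CRITERIA})
        values = list(flags)
        if len(values) != len(CRITERIA):
            raise DataError(f"expected {len(CRITERIA)} criterion flags, got {len(values)}")
        return cls(**{name: bool(v) for name, v in zip(CRITERIA, values)})


def criterion_count(record: CriteriaRecord) -> int:
    """Number of satisfied criteria, in [0, 11]."""
    return sum(getattr(record, name) for name in CRITERIA)


def classify_sle(record: CriteriaRecord) -> bool:
    """Confirmed SLE iff at least 4 of the 11 criteria are satisfied."""
    return criterion_count(record) >= SLE_CRITERION_THRESHOLD


def criterion_count_frame(frame: pd.DataFrame) -> pd.Series:
    """Vectorised criterion count over a verification frame."""
    return frame[list(CRITERIA)].sum(axis=1)


def classify_sle_frame(frame: pd.DataFrame) -> pd.Series:
    """Vectorised classification over a verification frame."""
    return criterion_count_frame(frame) >= SLE_CRITERION_THRESHOLD


def read_verification(path) -> pd.DataFrame:
    """Read and validate a verification CSV.

    Expects ``patient_id`` plus the eleven criterion columns named exactly
    as in :data:`CRITERIA`, with 0/1 values.  Missing cells and values
    other than 0/1 are rejected outright — partially completed review
    forms are not imputed, since imputation would bias the PPV.
    """
    frame = pd.read_csv(path)
    missing = [c for c in ("patient_id",) + CRITERIA if c not in frame.columns]
    if missing:
        raise SchemaError(f"verification table missing required column(s): {missing}")
    frame = frame[["patient_id"] + list(CRITERIA)].copy()
    frame["patient_id"] = frame["patient_id"].astype(str)
    for column in CRITERIA:
        values = frame[column]
        if values.isna().any():
            i = frame.index[values.isna()][0]
            raise DataError(
                f"missing value for criterion {column!r} at row {i}; "
                "partially completed verification forms are rejected"
            )
        if not values.isin((0, 1, True, False)).all():
            i = frame.index[~values.isin((0, 1, True, False))][0]
            raise DataError(
                f"criterion {column!r} must be 0/1, got {values[i]!r} at row {i}"
            )
        frame[column] = values.astype(int)
    return frame
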