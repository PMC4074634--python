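"""Claims data model, I/O and patient-level deduplication.

The unit of raw data is one billing event: a patient identifier together
with the calendar year of the claim and the demographic / institutional
strata recorded by the insurer (region, hospital type, department, service
type, age, sex).  Analysis happens at the patient level: claims are
deduplicated into one summary row per patient carrying the set of study
years in which that patient was billed and a visit-pattern label derived
from it.

Claims tables are held as :class:`pandas.DataFrame` objects with the
canonical columns in :data:`CLAIMS_COLUMNS`; :class:`ClaimRecord` is the
row-level view.  All categorical columns use closed vocabularies — unknown
values are rejected at parse time rather than silently propagated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("claimprev")

# ---------------------------------------------------------------------------
# Closed vocabularies
# ---------------------------------------------------------------------------

REGIONS = ("Seoul", "Kyounggi", "Pusan", "Daegu", "Jeju", "other")
HOSPITAL_TYPES = ("private_clinic", "local_hospital", "general_hospital", "university_hospital")
DEPARTMENTS = ("rheumatology", "dermatology", "pediatrics", "other")
SERVICE_TYPES = ("admission", "outpatient")
SEXES = ("female", "male")

CLAIMS_COLUMNS = (
    "patient_id",
    "billing_year",
    "region",
    "hospital_type",
    "department",
    "service_type",
    "age_years",
    "sex",
)

_VOCABULARIES = {
    "region": REGIONS,
    "hospital_type": HOSPITAL_TYPES,
    "department": DEPARTMENTS,
    "service_type": SERVICE_TYPES,
    "sex": SEXES,
}

#: Columns of a patient-summary frame produced by :func:`deduplicate`.
PATIENT_COLUMNS = (
    "patient_id",
    "years_billed",
    "visit_pattern",
    "region",
    "hospital_type",
    "department",
    "sex",
    "age_at_first_claim",
)

AGE_DECADE_LABELS = ("0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")


class SchemaError(ValueError):
    """A table violates the expected schema (missing column, unknown category)."""


class DataError(ValueError):
    """Row-level values could not be parsed or violate an invariant."""


# ---------------------------------------------------------------------------
# Study window
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyWindow:
    """Three consecutive calendar years labelled a < b < c.

    The visit-pattern notation (labels ``a``/``b``/``c`` and their
    concatenations) is tied to a three-year window; the default window is
    2004–2006.
    """

    year_a: int = 2004
    year_b: int = 2005
    year_c: int = 2006

    def __post_init__(self) -> None:
        if not (self.year_b == self.year_a + 1 and self.year_c == self.year_b + 1):
            raise ValueError(
                f"study window years must be consecutive and increasing, "
                f"got ({self.year_a}, {self.year_b}, {self.year_c})"
            )

    @property
    def years(self) -> tuple[int, int, int]:
        return (self.year_a, self.year_b, self.year_c)

    @property
    def letters(self) -> tuple[str, str, str]:
        return ("a", "b", "c")

    def letter_for_year(self, year: int) -> str:
        try:
            return self.letters[self.years.index(year)]
        except ValueError:
            raise ValueError(f"year {year} outside study window {self.years}") from None

    def __contains__(self, year: object) -> bool:
        return year in self.years


# ---------------------------------------------------------------------------
# Row-level record
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClaimRecord:
    """One billing event for one patient."""

    patient_id: str
    billing_year: int
    region: str
    hospital_type: str
    department: str
    service_type: str
    age_years: int
    sex: str

    def __post_init__(self) -> None:
        for column, vocabulary in _VOCABULARIES.items():
            value = getattr(self, column)
            if value not in vocabulary:
                raise SchemaError(
                    f"unknown {column} value {value!r}; expected one of {vocabulary}"
                )
        if not 0 <= self.age_years <= 120:
            raise DataError(f"age_years {self.age_years} outside [0, 120]")


def claims_to_frame(records: Iterable[ClaimRecord]) -> pd.DataFrame:
    """Build a canonical claims frame from :class:`ClaimRecord` objects."""
    rows = [
        (r.patient_id, r.billing_year, r.region, r.hospital_type, r.department,
         r.service_type, r.age_years, r.sex)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CLAIMS_COLUMNS))


def claims_from_frame(frame: pd.DataFrame) -> list[ClaimRecord]:
    """Row-level view of a claims frame (validates each row)."""
    return [ClaimRecord(**row) for row in frame[list(CLAIMS_COLUMNS)].to_dict("records")]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _validate_claims_frame(frame: pd.DataFrame, window: StudyWindow | None) -> pd.DataFrame:
    missing = [c for c in CLAIMS_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"claims table missing required column(s): {missing}")
    frame = frame[list(CLAIMS_COLUMNS)].copy()

    row_errors: list[str] = []
    for column in ("billing_year", "age_years"):
        converted = pd.to_numeric(frame[column], errors="coerce")
        bad = frame.index[converted.isna()]
        for i in bad[:5]:
            row_errors.append(f"row {i}: unparseable {column} value {frame.at[i, column]!r}")
        if len(bad) > 5:
            row_errors.append(f"... and {len(bad) - 5} more unparseable {column} rows")
        frame[column] = converted
    if row_errors:
        raise DataError(f"{len(row_errors)} row-level error(s):\n" + "\n".join(row_errors))
    frame["billing_year"] = frame["billing_year"].astype(np.int64)
    frame["age_years"] = frame["age_years"].astype(np.int64)

    out_of_range = frame.index[(frame["age_years"] < 0) | (frame["age_years"] > 120)]
    if len(out_of_range):
        i = out_of_range[0]
        raise DataError(
            f"{len(out_of_range)} row(s) with age_years outside [0, 120]; "
            f"first at row {i} (value {frame.at[i, 'age_years']})"
        )

    frame["patient_id"] = frame["patient_id"].astype(str)
    for column, vocabulary in _VOCABULARIES.items():
        values = frame[column].astype(str)
        bad_mask = ~values.isin(vocabulary)
        if bad_mask.any():
            i = frame.index[bad_mask][0]
            raise SchemaError(
                f"unknown {column} value {values[i]!r} at row {i}; "
                f"expected one of {vocabulary} ({int(bad_mask.sum())} offending row(s))"
            )
        frame[column] = values

    if window is not None:
        outside = ~frame["billing_year"].isin(window.years)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} claim(s) billed outside study window "
                f"{window.years}; they are ignored by deduplication",
                stacklevel=3,
            )
    return frame


def read_claims(path, window: StudyWindow | None = None) -> pd.DataFrame:
    """Read and validate a claims CSV.

    Parameters
    ----------
    path
        CSV file with header row naming all of :data:`CLAIMS_COLUMNS`
        (comma-separated, UTF-8).
    window
        If given, claims billed outside the window are flagged with a
        warning (they are excluded later, by :func:`deduplicate`).

    Raises
    ------
    SchemaError
        Missing column or a categorical value outside its closed
        vocabulary (the error names the row and column).
    DataError
        Unparseable year/age values or an age outside [0, 120].
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    validated = _validate_claims_frame(frame, window)
    logger.info("read_claims: %d claim rows from %s", len(validated), path)
    return validated


def write_claims(frame: pd.DataFrame, path) -> None:
    """Write a claims frame as canonical CSV (column order fixed)."""
    frame[list(CLAIMS_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Deduplication: claims -> one summary per patient
# ---------------------------------------------------------------------------

_YEAR_SET_FOR_MASK: dict[int, frozenset] = {}
_PATTERN_FOR_MASK = {
    0b001: "a", 0b010: "b", 0b100: "c",
    0b011: "ab", 0b101: "ac", 0b110: "bc", 0b111: "abc",
}


def _modal_first_observed(frame: pd.DataFrame, column: str) -> pd.Series:
    """Per-patient modal value of `column`; ties broken by first observation."""
    counts = (
        frame.groupby(["patient_id", column], sort=False)
        .agg(n=("_order", "size"), first_seen=("_order", "min"))
        .reset_index()
        .sort_values(["n", "first_seen"], ascending=[False, True], kind="mergesort")
        .drop_duplicates("patient_id")
        .set_index("patient_id")[column]
    )
    return counts


def deduplicate(claims, window: StudyWindow | None = None) -> pd.DataFrame:
    """Collapse billing events into one summary row per patient.

    ``years_billed`` is the set of distinct billing years observed within
    the window; the visit-pattern label is the chronological concatenation
    of the year letters (see :mod:`claimprev.visit_patterns`).  Demographic
    attributes that conflict across a patient's claims are resolved to the
    modal value, ties broken by first observation, with a warning.

    Accepts either a canonical claims frame or a sequence of
    :class:`ClaimRecord`.
    """
    if window is None:
        window = StudyWindow()
    if not isinstance(claims, pd.DataFrame):
        claims = claims_to_frame(claims)
    if len(claims) == 0:
        raise DataError("deduplicate: empty claims input")

    frame = claims[claims["billing_year"].isin(window.years)]
    if len(frame) == 0:
        raise DataError(f"deduplicate: no claims within study window {window.years}")
    frame = frame.reset_index(drop=True)

    # Year-set as a 3-bit mask per patient (bit i = window year i billed).
    year_index = frame["billing_year"].map({y: i for i, y in enumerate(window.years)})
    bits = (1 << year_index.to_numpy()).astype(np.int64)
    patient_year = pd.DataFrame(
        {"patient_id": frame["patient_id"], "_bit": bits}
    ).drop_duplicates(["patient_id", "_bit"])
    mask = patient_year.groupby("patient_id", sort=False)["_bit"].sum()

    # Attributes: fast path when constant per patient, modal path otherwise.
    n_patients = mask.size
    first_rows = frame.drop_duplicates("patient_id").set_index("patient_id")
    attrs: dict[str, pd.Series] = {}
    order_added = False
    for column in ("region", "hospital_type", "department", "sex"):
        n_distinct = len(frame[["patient_id", column]].drop_duplicates())
        if n_distinct == n_patients:
            attrs[column] = first_rows[column]
        else:
            if not order_added:
                frame = frame.assign(_order=np.arange(len(frame)))
                order_added = True
            warnings.warn(
                f"conflicting {column} values for "
                f"{n_distinct - n_patients} patient(s); keeping modal value "
                f"(first observed on tie)",
                stacklevel=2,
            )
            attrs[column] = _modal_first_observed(frame, column)

    # Age at the earliest claim (stable order within a year keeps this
    # deterministic for duplicated patient-years).
    earliest = frame.sort_values("billing_year", kind="mergesort").drop_duplicates("patient_id")
    age_first = earliest.set_index("patient_id")["age_years"]

    year_sets = {
        m: frozenset(y for i, y in enumerate(window.years) if m >> i & 1)
        for m in range(1, 8)
    }
    patients = pd.DataFrame(
        {
            "patient_id": mask.index,
            "years_billed": mask.map(year_sets).to_numpy(),
            "visit_pattern": mask.map(_PATTERN_FOR_MASK).to_numpy(),
            "region": attrs["region"].reindex(mask.index).to_numpy(),
            "hospital_type": attrs["hospital_type"].reindex(mask.index).to_numpy(),
            "department": attrs["department"].reindex(mask.index).to_numpy(),
            "sex": attrs["sex"].reindex(mask.index).to_numpy(),
            "age_at_first_claim": age_first.reindex(mask.index).to_numpy(),
        }
    ).reset_index(drop=True)
    logger.info("deduplicate: %d claims -> %d unique patients", len(frame), len(patients))
    return patients


def patients_to_claims(patients: pd.DataFrame) -> pd.DataFrame:
    """Re-encode patient summaries as one claim per billed year.

    Inverse-direction helper used for round-trip / idempotence checks and
    for feeding summary-level data back through claim-level tooling.
    """
    rows = []
    for row in patients.itertuples(index=False):
        for year in sorted(row.years_billed):
            rows.append(
                (row.patient_id, year, row.region, row.hospital_type,
                 row.department, "outpatient", row.age_at_first_claim, row.sex)
            )
    return pd.DataFrame(rows, columns=list(CLAIMS_COLUMNS))


# ---------------------------------------------------------------------------
# Stratum tabulation
# ---------------------------------------------------------------------------


def age_decade(ages: Sequence[int] | pd.Series) -> pd.Series:
    """Map ages in years to decade labels '0-9' … '80+'."""
    ages = pd.Series(ages)
    idx = np.minimum(ages.to_numpy() // 10, 8)
    return pd.Series(np.asarray(AGE_DECADE_LABELS)[idx], index=ages.index)


def tabulate_strata(patients: pd.DataFrame) -> dict[str, pd.Series]:
    """Marginal patient counts by region, hospital type, sex and age decade.

    Every marginal table sums to the number of patients (zero-count
    categories are kept so the vocabularies stay visible).
    """
    tables: dict[str, pd.Series] = {}
    for column, vocabulary in (
        ("region", REGIONS),
        ("hospital_type", HOSPITAL_TYPES),
        ("sex", SEXES),
    ):
        counts = (
            patients[column].value_counts().reindex(vocabulary, fill_value=0).astype(int)
            if len(patients)
            else pd.Series(0, index=list(vocabulary), dtype=int)
        )
        counts.name = column
        tables[column] = counts
    if len(patients):
        decades = age_decade(patients["age_at_first_claim"])
        tables["age_decade"] = (
            decades.value_counts().reindex(AGE_DECADE_LABELS, fill_value=0).astype(int)
        )
    else:
        tables["age_decade"] = pd.Series(0, index=list(AGE_DECADE_LABELS), dtype=int)
    tables["age_decade"].name = "age_decade"
    return tables
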