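"""ED encounter data model, CSV round-trip, and the cohort exclusion filter.

One :class:`EncounterRecord` represents a single emergency-department visit
as captured at triage: vital signs, the Manchester Triage System (MTS)
category the nurse assigned, the nurse checkboxes of the SIRS-based
screening form, order flags used as suspected-infection proxies, SOFA
component scores, and in-hospital outcomes.

The canonical on-disk format is a flat CSV with one column per field
(vitals flattened), empty string meaning *missing* and booleans encoded
0/1.  Reading never imputes: a missing cell stays missing on the record.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "TriageCategory",
    "Avpu",
    "Vitals",
    "EncounterRecord",
    "ExclusionReport",
    "CohortParseError",
    "RowError",
    "COHORT_COLUMNS",
    "SOFA_COMPONENT_NAMES",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
]


class TriageCategory(str, Enum):
    """MTS urgency codes plus the dedicated possible-sepsis category.

    The digital MTS implementation audited here exposes "possible sepsis"
    as its own assignable category (it fires the MTS sepsis alert), so it
    is modelled as a sixth disjoint value rather than a flag.
    """

    BLUE = "blue"                      # non-urgent, 240 min
    GREEN = "green"                    # standard, 120 min
    YELLOW = "yellow"                  # urgent, 60 min
    ORANGE = "orange"                  # very urgent, 10 min
    POSSIBLE_SEPSIS = "possible_sepsis"
    RED = "red"                        # immediate


class Avpu(str, Enum):
    ALERT = "A"
    VOICE = "V"
    PAIN = "P"
    UNRESPONSIVE = "U"


@dataclass(frozen=True)
class Vitals:
    """Triage vital signs; every field is optional (empty EHR cell).

    ``altered_mental_checkbox`` is the nurse-entered altered-mental-state
    checkbox of the SIRS screening form.  It is tri-state: ``True`` /
    ``False`` when the form was answered, ``None`` when not recorded.
    """

    temp_c: Optional[float] = None
    heart_rate: Optional[float] = None
    resp_rate: Optional[float] = None
    sbp: Optional[float] = None
    gcs: Optional[int] = None
    avpu: Optional[Avpu] = None
    spo2: Optional[float] = None
    supplemental_o2: Optional[bool] = None
    altered_mental_checkbox: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            raise ValueError(f"gcs must be in [3, 15], got {self.gcs}")
        if self.spo2 is not None and not 0 <= self.spo2 <= 100:
            raise ValueError(f"spo2 must be in [0, 100], got {self.spo2}")
        for name in ("temp_c", "heart_rate", "resp_rate", "sbp"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")


SOFA_COMPONENT_NAMES: tuple[str, ...] = (
    "sofa_respiratory",
    "sofa_coagulation",
    "sofa_liver",
    "sofa_cardiovascular",
    "sofa_cns",
    "sofa_renal",
)

_NO_SOFA: tuple[Optional[int], ...] = (None,) * 6


@dataclass(frozen=True)
class EncounterRecord:
    """One ED visit as extracted from the EHR at triage."""

    encounter_id: str
    triage_category: TriageCategory
    age_years: Optional[float] = None
    vitals: Vitals = Vitals()
    suspicion_new_infection: Optional[bool] = None
    antibiotics_ordered: bool = False
    blood_cultures_ordered: bool = False
    sofa_components: tuple[Optional[int], ...] = _NO_SOFA
    sofa_total_precomputed: Optional[int] = None
    lactate_mmol_l: Optional[float] = None
    vasopressors: Optional[bool] = None
    palliative_pathway: bool = False
    icu_within_24h: bool = False
    icu_within_72h: bool = False
    died_in_hospital: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.triage_category, TriageCategory):
            raise ValueError(f"unknown triage category: {self.triage_category!r}")
        if len(self.sofa_components) != 6:
            raise ValueError("sofa_components must have exactly 6 entries")
        for score in self.sofa_components:
            if score is not None and not 0 <= score <= 4:
                raise ValueError(f"SOFA component must be in [0, 4], got {score}")
        if self.sofa_total_precomputed is not None and not (
            0 <= self.sofa_total_precomputed <= 24
        ):
            raise ValueError("sofa_total must be in [0, 24]")


@dataclass(frozen=True)
class ExclusionReport:
    """Accounting of the cohort exclusion filter (blue first, then palliative)."""

    n_input: int
    n_blue_excluded: int
    n_palliative_excluded: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_retained != (
            self.n_input - self.n_blue_excluded - self.n_palliative_excluded
        ):
            raise ValueError("exclusion counts do not sum: "
                             f"{self.n_input} - {self.n_blue_excluded} - "
                             f"{self.n_palliative_excluded} != {self.n_retained}")


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

COHORT_COLUMNS: tuple[str, ...] = (
    "encounter_id",
    "age_years",
    "triage_category",
    "temp_c",
    "heart_rate",
    "resp_rate",
    "sbp",
    "gcs",
    "avpu",
    "spo2",
    "supplemental_o2",
    "altered_mental",
    "suspicion_new_infection",
    "antibiotics_ordered",
    "blood_cultures_ordered",
    *SOFA_COMPONENT_NAMES,
    "sofa_total",
    "lactate_mmol_l",
    "vasopressors",
    "palliative_pathway",
    "icu_within_24h",
    "icu_within_72h",
    "died_in_hospital",
)

# Required booleans default to False on an empty cell (EHR checkbox default
# is unchecked); tri-state booleans stay None so missingness is reportable.
_TRISTATE_BOOLS = frozenset(
    {"supplemental_o2", "altered_mental", "suspicion_new_infection", "vasopressors"}
)
_REQUIRED_BOOLS = frozenset(
    {
        "antibiotics_ordered",
        "blood_cultures_ordered",
        "palliative_pathway",
        "icu_within_24h",
        "icu_within_72h",
        "died_in_hospital",
    }
)
_FLOAT_FIELDS = frozenset(
    {"age_years", "temp_c", "heart_rate", "resp_rate", "sbp", "spo2", "lactate_mmol_l"}
)
_INT_FIELDS = frozenset({"gcs", "sofa_total", *SOFA_COMPONENT_NAMES})

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


@dataclass(frozen=True)
class RowError:
    """A row-level parse failure: CSV line number, column, offending value."""

    row_number: int
    column: str
    value: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row_number}, column {self.column!r}: {self.message} ({self.value!r})"


class CohortParseError(ValueError):
    """Raised when one or more CSV rows cannot be parsed."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        summary = "; ".join(str(e) for e in self.errors[:5])
        more = f" (+{len(self.errors) - 5} more)" if len(self.errors) > 5 else ""
        super().__init__(f"{len(self.errors)} bad row(s): {summary}{more}")


def _parse_cell(column: str, raw: str, row_number: int, errors: list[RowError]):
    text = raw.strip()
    if text == "":
        return False if column in _REQUIRED_BOOLS else None
    try:
        if column in _FLOAT_FIELDS:
            return float(text)
        if column in _INT_FIELDS:
            return int(float(text))
        if column in _TRISTATE_BOOLS or column in _REQUIRED_BOOLS:
            low = text.lower()
            if low in _TRUE:
                return True
            if low in _FALSE:
                return False
            raise ValueError("not a 0/1 boolean")
        if column == "triage_category":
            return TriageCategory(text)
        if column == "avpu":
            return Avpu(text.upper())
        return text  # encounter_id
    except ValueError as exc:
        errors.append(RowError(row_number, column, text, str(exc) or "malformed value"))
        return None


def read_cohort(
    path: str | Path,
    dialect: str | csv.Dialect = "excel",
    column_map: Optional[Mapping[str, str]] = None,
) -> list[EncounterRecord]:
    """Read a cohort CSV into :class:`EncounterRecord` objects.

    Parameters
    ----------
    path:
        CSV file with a header row naming every column of
        :data:`COHORT_COLUMNS` (extra columns are ignored).
    dialect:
        Any :mod:`csv` dialect.
    column_map:
        Optional mapping ``{canonical_name: header_name_in_file}`` for
        extracts whose headers differ from the documented names.

    Raises
    ------
    CohortParseError
        If any row has an unknown triage category or a malformed value;
        every offending row is reported with its line number.
    """
    column_map = dict(column_map or {})
    errors: list[RowError] = []
    records: list[EncounterRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, dialect=dialect)
        header = set(reader.fieldnames or ())
        missing_cols = [
            column_map.get(c, c) for c in ("encounter_id", "triage_category")
            if column_map.get(c, c) not in header
        ]
        if missing_cols:
            raise CohortParseError(
                [RowError(1, c, "", "required column missing from header") for c in missing_cols]
            )
        for row_number, row in enumerate(reader, start=2):
            n_before = len(errors)
            parsed = {}
            for column in COHORT_COLUMNS:
                source = column_map.get(column, column)
                parsed[column] = _parse_cell(column, row.get(source, ""), row_number, errors)
            if len(errors) > n_before:
                continue  # reject the whole row
            if parsed["encounter_id"] is None:
                errors.append(RowError(row_number, "encounter_id", "", "empty encounter id"))
                continue
            if parsed["triage_category"] is None:
                errors.append(
                    RowError(row_number, "triage_category", "", "empty triage category")
                )
                continue
            vitals = Vitals(
                temp_c=parsed["temp_c"],
                heart_rate=parsed["heart_rate"],
                resp_rate=parsed["resp_rate"],
                sbp=parsed["sbp"],
                gcs=parsed["gcs"],
                avpu=parsed["avpu"],
                spo2=parsed["spo2"],
                supplemental_o2=parsed["supplemental_o2"],
                altered_mental_checkbox=parsed["altered_mental"],
            )
            records.append(
                EncounterRecord(
                    encounter_id=parsed["encounter_id"],
                    age_years=parsed["age_years"],
                    triage_category=parsed["triage_category"],
                    vitals=vitals,
                    suspicion_new_infection=parsed["suspicion_new_infection"],
                    antibiotics_ordered=parsed["antibiotics_ordered"],
                    blood_cultures_ordered=parsed["blood_cultures_ordered"],
                    sofa_components=tuple(parsed[c] for c in SOFA_COMPONENT_NAMES),
                    sofa_total_precomputed=parsed["sofa_total"],
                    lactate_mmol_l=parsed["lactate_mmol_l"],
                    vasopressors=parsed["vasopressors"],
                    palliative_pathway=parsed["palliative_pathway"],
                    icu_within_24h=parsed["icu_within_24h"],
                    icu_within_72h=parsed["icu_within_72h"],
                    died_in_hospital=parsed["died_in_hospital"],
                )
            )
    if errors:
        raise CohortParseError(errors)
    return records


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def record_to_row(rec: EncounterRecord) -> dict[str, str]:
    """Flatten one record to the documented CSV row."""
    v = rec.vitals
    row = {
        "encounter_id": rec.encounter_id,
        "age_years": rec.age_years,
        "triage_category": rec.triage_category,
        "temp_c": v.temp_c,
        "heart_rate": v.heart_rate,
        "resp_rate": v.resp_rate,
        "sbp": v.sbp,
        "gcs": v.gcs,
        "avpu": v.avpu,
        "spo2": v.spo2,
        "supplemental_o2": v.supplemental_o2,
        "altered_mental": v.altered_mental_checkbox,
        "suspicion_new_infection": rec.suspicion_new_infection,
        "antibiotics_ordered": rec.antibiotics_ordered,
        "blood_cultures_ordered": rec.blood_cultures_ordered,
        **dict(zip(SOFA_COMPONENT_NAMES, rec.sofa_components)),
        "sofa_total": rec.sofa_total_precomputed,
        "lactate_mmol_l": rec.lactate_mmol_l,
        "vasopressors": rec.vasopressors,
        "palliative_pathway": rec.palliative_pathway,
        "icu_within_24h": rec.icu_within_24h,
        "icu_within_72h": rec.icu_within_72h,
        "died_in_hospital": rec.died_in_hospital,
    }
    return {k: _format_cell(val) for k, val in row.items()}


def write_cohort(records: Iterable[EncounterRecord], path: str | Path) -> None:
    """Write records to CSV; ``read_cohort`` of the output round-trips exactly."""
    with open(path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=COHORT_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for rec in records:
            writer.writerow(record_to_row(rec))


# ---------------------------------------------------------------------------
# Exclusion filter
# ---------------------------------------------------------------------------

def apply_exclusions(
    records: Sequence[EncounterRecord],
) -> tuple[list[EncounterRecord], ExclusionReport]:
    """Drop blue-category and palliative-pathway encounters.

    Blue-category visits are excluded first (no sepsis occurred in that
    category), then immediate-palliative-care visits; a record that is
    both is counted once, under blue.  Idempotent.
    """
    retained: list[EncounterRecord] = []
    n_blue = 0
    n_palliative = 0
    for rec in records:
        if rec.triage_category is TriageCategory.BLUE:
            n_blue += 1
        elif rec.palliative_pathway:
            n_palliative += 1
        else:
            retained.append(rec)
    report = ExclusionReport(
        n_input=len(records),
        n_blue_excluded=n_blue,
        n_palliative_excluded=n_palliative,
        n_retained=len(retained),
    )
    return retained, report
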