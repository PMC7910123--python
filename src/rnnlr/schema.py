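"""EHR cohort data model for post-peritonitis-surgery complication prediction.

A cohort is a set of patients, each with static demographics/comorbidity
flags and 1-3 timestamped laboratory records collected in the three-day
window after surgery (day 0 = surgery day, days 0/1/2), labelled with one of
three outcomes: ``neither``, ``AHE`` (acute hepatic encephalopathy) or
``HRS`` (hepatorenal syndrome).

On disk a cohort is a single flat CSV, one row per clinical record, with
patient-level columns repeated on each of the patient's rows and an empty
cell denoting a missing laboratory value (never ``0``).  The full column
dictionary is :data:`COLUMN_DICTIONARY`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteDefinition", "ClinicalRecord", "PatientHistory", "Cohort",
    "CLASS_ORDER", "CHARLSON_CATEGORIES", "N_OPERATION_CATEGORIES",
    "WINDOW_DAYS", "default_panel", "load_panel",
    "read_cohort", "write_cohort", "validate_cohort",
    "SchemaError", "ConsistencyError", "WindowError", "Violation",
]

CLASS_ORDER: tuple[str, str, str] = ("neither", "AHE", "HRS")

#: Collection window in whole days after surgery; day offsets are 0-based,
#: half-open [0, WINDOW_DAYS).
WINDOW_DAYS = 3

#: The 17 Charlson comorbidity categories used as boolean patient flags.
CHARLSON_CATEGORIES: tuple[str, ...] = (
    "myocardial_infarction", "congestive_heart_failure",
    "peripheral_vascular_disease", "cerebrovascular_disease", "dementia",
    "chronic_pulmonary_disease", "rheumatologic_disease",
    "peptic_ulcer_disease", "mild_liver_disease", "diabetes",
    "diabetes_with_complications", "hemiplegia_paraplegia", "renal_disease",
    "malignancy", "moderate_severe_liver_disease", "metastatic_solid_tumor",
    "aids",
)

N_OPERATION_CATEGORIES = 7  # ICD-9-CM derived surgery categories, coded 0-6

AGE_RANGE = (0, 102)
DGTM_RANGE = (0, 136)


class SchemaError(ValueError):
    """CSV header or cell does not match the column dictionary."""


class ConsistencyError(ValueError):
    """Patient-level values disagree across one patient's rows."""


class WindowError(ValueError):
    """More records than the collection window admits."""


@dataclass(frozen=True)
class AnalyteDefinition:
    """A laboratory analyte with its clinically valid closed range."""

    name: str
    valid_range: tuple[float, float]
    units: str = ""

    def __post_init__(self):
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError(f"analyte {self.name}: range lower bound must be < upper")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.valid_range[0] + self.valid_range[1])

    @property
    def width(self) -> float:
        return self.valid_range[1] - self.valid_range[0]


@dataclass
class ClinicalRecord:
    """One timestamped laboratory draw; absent keys in ``labs`` are missing."""

    day_offset: int
    labs: dict[str, float] = field(default_factory=dict)


@dataclass
class PatientHistory:
    patient_id: str
    inpatient_id: str
    sex: int
    age: int
    dgtm: int  # hospitalizations before peritonitis surgery
    comorbidities: frozenset[str]
    operation_category: int
    pneumonia: bool
    uti: bool
    ssi: bool
    records: list[ClinicalRecord]
    outcome: str
    onset_day: int | None = None  # complication onset, days post surgery
    length_of_stay: float | None = None


@dataclass
class Cohort:
    patients: list[PatientHistory]
    panel: list[AnalyteDefinition]
    class_order: tuple[str, str, str] = CLASS_ORDER

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def n_records(self) -> int:
        return sum(len(p.records) for p in self.patients)

    def analyte(self, name: str) -> AnalyteDefinition:
        for a in self.panel:
            if a.name == name:
                return a
        raise KeyError(name)

    def copy(self) -> "Cohort":
        patients = [
            replace(p, records=[ClinicalRecord(r.day_offset, dict(r.labs))
                                for r in p.records])
            for p in self.patients
        ]
        return Cohort(patients, list(self.panel), self.class_order)


def default_panel() -> list[AnalyteDefinition]:
    """The 18-analyte laboratory panel bundled with the package."""
    with resources.files("rnnlr.data").joinpath("analyte_panel.json").open() as fh:
        return _panel_from_json(json.load(fh))


def load_panel(path: str | Path) -> list[AnalyteDefinition]:
    """Read an analyte-panel definition from a JSON file."""
    with open(path) as fh:
        return _panel_from_json(json.load(fh))


def _panel_from_json(entries: list[dict]) -> list[AnalyteDefinition]:
    return [AnalyteDefinition(d["name"], (float(d["low"]), float(d["high"])),
                              d.get("units", "")) for d in entries]


# ---------------------------------------------------------------------------
# CSV layer
# ---------------------------------------------------------------------------

_STATIC_COLS = (
    ["patient_id", "inpatient_id", "sex", "age", "dgtm"]
    + [f"cm_{c}" for c in CHARLSON_CATEGORIES]
    + ["operation_category", "pneumonia", "uti", "ssi",
       "outcome", "onset_day", "length_of_stay"]
)


def _lab_col(name: str) -> str:
    return f"lab_{name}"


def column_dictionary(panel: list[AnalyteDefinition]) -> list[str]:
    """Ordered CSV header for a cohort file with the given panel (one row
    per clinical record; patient-level columns repeated per row)."""
    return _STATIC_COLS + ["day_offset"] + [_lab_col(a.name) for a in panel]


def _parse_outcome(raw: str) -> str:
    key = str(raw).strip().lower()
    for label in CLASS_ORDER:
        if key == label.lower():
            return label
    raise SchemaError(f"unknown outcome label {raw!r}; expected one of {CLASS_ORDER}")


_MISSING_TOKENS = {"", "na", "nan", "none"}


def _cell_missing(v) -> bool:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return True
    return str(v).strip().lower() in _MISSING_TOKENS


def read_cohort(path: str | Path, panel: list[AnalyteDefinition] | None = None) -> Cohort:
    """Read a flat one-row-per-record cohort CSV.

    Rows are grouped by ``patient_id`` into :class:`PatientHistory` objects
    with records sorted ascending by ``day_offset``.  Patient-level columns
    must be identical across one patient's rows.  ``NA``/``NaN``/empty cells
    are accepted as missing lab values.
    """
    panel = panel if panel is not None else default_panel()
    expected = column_dictionary(panel)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown column(s) in cohort file: {unknown}")
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort file lacks column(s): {missing_cols}")

    patients: list[PatientHistory] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        statics = {}
        for col in _STATIC_COLS:
            vals = grp[col].unique()
            if len(vals) > 1:
                raise ConsistencyError(
                    f"patient {pid}: column {col} has conflicting values {list(vals)}")
            statics[col] = vals[0]
        if len(grp) > WINDOW_DAYS:
            raise WindowError(
                f"patient {pid}: {len(grp)} records exceed the {WINDOW_DAYS}-day window")
        records = []
        for _, row in grp.iterrows():
            labs = {}
            for a in panel:
                cell = row[_lab_col(a.name)]
                if not _cell_missing(cell):
                    labs[a.name] = float(cell)
            records.append(ClinicalRecord(int(row["day_offset"]), labs))
        records.sort(key=lambda r: r.day_offset)
        patients.append(PatientHistory(
            patient_id=str(pid),
            inpatient_id=str(statics["inpatient_id"]),
            sex=int(statics["sex"]),
            age=int(statics["age"]),
            dgtm=int(statics["dgtm"]),
            comorbidities=frozenset(
                c for c in CHARLSON_CATEGORIES if int(statics[f"cm_{c}"]) == 1),
            operation_category=int(statics["operation_category"]),
            pneumonia=bool(int(statics["pneumonia"])),
            uti=bool(int(statics["uti"])),
            ssi=bool(int(statics["ssi"])),
            records=records,
            outcome=_parse_outcome(statics["outcome"]),
            onset_day=None if _cell_missing(statics["onset_day"])
            else int(statics["onset_day"]),
            length_of_stay=None if _cell_missing(statics["length_of_stay"])
            else float(statics["length_of_stay"]),
        ))
    return Cohort(patients, panel)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as the flat one-row-per-record CSV.

    Missing lab values become empty cells (``read_cohort(write_cohort(c))``
    reproduces ``c`` exactly, including missingness).
    """
    cols = column_dictionary(cohort.panel)
    rows = []
    for p in cohort.patients:
        static = {
            "patient_id": p.patient_id, "inpatient_id": p.inpatient_id,
            "sex": p.sex, "age": p.age, "dgtm": p.dgtm,
            "operation_category": p.operation_category,
            "pneumonia": int(p.pneumonia), "uti": int(p.uti), "ssi": int(p.ssi),
            "outcome": p.outcome,
            "onset_day": "" if p.onset_day is None else p.onset_day,
            "length_of_stay": "" if p.length_of_stay is None else p.length_of_stay,
        }
        for c in CHARLSON_CATEGORIES:
            static[f"cm_{c}"] = int(c in p.comorbidities)
        for r in p.records:
            row = dict(static)
            row["day_offset"] = r.day_offset
            for a in cohort.panel:
                row[_lab_col(a.name)] = r.labs.get(a.name, "")
            rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    if not rows:  # header-only file for an empty cohort
        Path(path).write_text(",".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    patient_id: str
    field: str
    message: str


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every structural invariant and analyte range; report, never clip.

    Returns an empty list iff the cohort is valid.  Range checks are closed
    intervals (boundary values are valid).
    """
    out: list[Violation] = []
    if len(cohort.class_order) != 3:
        out.append(Violation("", "class_order", "class_order must have 3 labels"))
    seen_ids: set[str] = set()
    names = {a.name for a in cohort.panel}
    for p in cohort.patients:
        if p.patient_id in seen_ids:
            out.append(Violation(p.patient_id, "patient_id", "duplicate patient_id"))
        seen_ids.add(p.patient_id)
        if not 1 <= len(p.records) <= WINDOW_DAYS:
            out.append(Violation(p.patient_id, "records",
                                 f"patient must have 1-{WINDOW_DAYS} records, "
                                 f"found {len(p.records)}"))
        offsets = [r.day_offset for r in p.records]
        if offsets != sorted(offsets):
            out.append(Violation(p.patient_id, "records",
                                 "records not sorted by day_offset"))
        if not AGE_RANGE[0] <= p.age <= AGE_RANGE[1]:
            out.append(Violation(p.patient_id, "age",
                                 f"age {p.age} outside {AGE_RANGE}"))
        if not DGTM_RANGE[0] <= p.dgtm <= DGTM_RANGE[1]:
            out.append(Violation(p.patient_id, "dgtm",
                                 f"dgtm {p.dgtm} outside {DGTM_RANGE}"))
        if p.sex not in (0, 1):
            out.append(Violation(p.patient_id, "sex", f"sex {p.sex} not in (0, 1)"))
        if not 0 <= p.operation_category < N_OPERATION_CATEGORIES:
            out.append(Violation(p.patient_id, "operation_category",
                                 f"category {p.operation_category} outside 0-6"))
        if p.outcome not in cohort.class_order:
            out.append(Violation(p.patient_id, "outcome",
                                 f"outcome {p.outcome!r} not in class_order"))
        if not p.comorbidities <= set(CHARLSON_CATEGORIES):
            out.append(Violation(p.patient_id, "comorbidities",
                                 f"unknown categories {p.comorbidities - set(CHARLSON_CATEGORIES)}"))
        for idx, r in enumerate(p.records):
            if not 0 <= r.day_offset < WINDOW_DAYS:
                out.append(Violation(p.patient_id, f"records[{idx}].day_offset",
                                     f"day_offset {r.day_offset} outside [0, {WINDOW_DAYS})"))
            for name, value in r.labs.items():
                if name not in names:
                    out.append(Violation(p.patient_id, f"records[{idx}].{name}",
                                         "lab key is not a defined analyte"))
                    continue
                lo, hi = cohort.analyte(name).valid_range
                if not lo <= value <= hi:
                    out.append(Violation(
                        p.patient_id, f"records[{idx}].{name}",
                        f"value {value} outside range ({lo}-{hi})"))
    return out
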