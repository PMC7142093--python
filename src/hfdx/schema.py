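"""Clinical attribute schema, diagnosis labels, and patient-table I/O.

The default schema captures the 14 clinical and echocardiographic
attributes used for heart-failure phenotyping: demographics (age, sex),
the cardinal symptom/sign and history items, the NT-proBNP biomarker,
and the echocardiographic panel (LVEF, LAVI, LVMI, E/e', septal e',
TRV, GLS).  Any attribute value may be Missing (represented as ``None``);
Missing is never imputed here — what a Missing value *means* is decided
by the knowledge models that consume the records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "Diagnosis",
    "HF_LABELS",
    "Attribute",
    "AttributeSchema",
    "PatientRecord",
    "default_schema",
    "load_cohort",
    "save_cohort",
]

#: A patient attribute value: a number, a boolean, or Missing (None).
Value = Union[float, bool, None]


class Diagnosis(str, Enum):
    """The four diagnostic outcomes; declaration order is the canonical
    label order used for confusion matrices and majority-vote tie-breaks."""

    HFrEF = "HFrEF"
    HFmrEF = "HFmrEF"
    HFpEF = "HFpEF"
    NoHF = "NoHF"

    @property
    def is_hf(self) -> bool:
        return self is not Diagnosis.NoHF


#: The three heart-failure subtypes (everything but NoHF).
HF_LABELS = (Diagnosis.HFrEF, Diagnosis.HFmrEF, Diagnosis.HFpEF)


@dataclass(frozen=True)
class Attribute:
    """One column of the patient table.

    ``valid_range`` is a closed interval enforced at load time for
    continuous attributes; binary attributes have no range.
    """

    name: str
    kind: str  # "continuous" | "binary"
    units: str = ""
    valid_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise SchemaError(f"unknown attribute kind {self.kind!r}")
        if self.kind == "continuous" and self.valid_range is None:
            raise SchemaError(f"continuous attribute {self.name!r} needs a valid_range")

    @property
    def is_binary(self) -> bool:
        return self.kind == "binary"


@dataclass(frozen=True)
class AttributeSchema:
    """An ordered, name-unique collection of attributes."""

    attributes: tuple[Attribute, ...]
    _by_name: Mapping[str, Attribute] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SchemaError("attribute names must be unique")
        object.__setattr__(self, "_by_name", {a.name: a for a in self.attributes})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Attribute:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown attribute {name!r}") from None

    def __iter__(self):
        return iter(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def check_value(self, name: str, value: Value, where: str = "") -> Value:
        """Validate (and return) one value against its attribute."""
        attr = self[name]
        ctx = f" ({where})" if where else ""
        if value is None:
            return None
        if attr.is_binary:
            if isinstance(value, bool):
                return value
            raise ValidationError(f"attribute {name!r} expects true/false, got {value!r}{ctx}")
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValidationError(f"attribute {name!r} expects a number, got {value!r}{ctx}")
        value = float(value)
        if math.isnan(value):
            return None
        lo, hi = attr.valid_range
        if not (lo <= value <= hi):
            raise ValidationError(
                f"attribute {name!r} value {value} outside valid range [{lo}, {hi}]{ctx}"
            )
        return value


def default_schema() -> AttributeSchema:
    """The 14-attribute heart-failure schema.

    LVEF and GLS are stored in percent (27.1, not 0.271); GLS as the
    magnitude of the (negative) strain, matching how echo reports print it.
    """
    return AttributeSchema(
        (
            Attribute("age", "continuous", "years", (0.0, 120.0)),
            Attribute("male", "binary"),
            Attribute("hf_symptoms_signs", "binary"),
            Attribute("clinical_history", "binary"),
            Attribute("physical_exam", "binary"),
            Attribute("abnormal_ecg", "binary"),
            Attribute("nt_probnp", "continuous", "pg/L", (0.0, 200000.0)),
            Attribute("lvef", "continuous", "%", (0.0, 100.0)),
            Attribute("lavi", "continuous", "mL/m2", (0.0, 200.0)),
            Attribute("lvmi", "continuous", "mg/m2", (0.0, 400.0)),
            Attribute("e_over_eprime", "continuous", "", (0.0, 80.0)),
            Attribute("septal_eprime", "continuous", "cm/s", (0.0, 25.0)),
            Attribute("trv", "continuous", "m/s", (0.0, 8.0)),
            Attribute("gls", "continuous", "%", (0.0, 40.0)),
        )
    )


@dataclass
class PatientRecord:
    """One patient: an id, one value per schema attribute (possibly
    Missing), and an optional gold-standard diagnosis."""

    patient_id: str
    values: dict[str, Value]
    gold_diagnosis: Optional[Diagnosis] = None

    def get(self, name: str) -> Value:
        return self.values.get(name)

    def is_missing(self, name: str) -> bool:
        return self.values.get(name) is None

    def masked(self, names: Sequence[str]) -> "PatientRecord":
        """A copy with the given attributes set to Missing."""
        vals = dict(self.values)
        for n in names:
            vals[n] = None
        return PatientRecord(self.patient_id, vals, self.gold_diagnosis)

    def validate(self, schema: AttributeSchema) -> "PatientRecord":
        for name in schema.names:
            self.values[name] = schema.check_value(
                name, self.values.get(name), where=f"patient {self.patient_id}"
            )
        return self


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}

#: Reserved (non-attribute) column names in patient CSV tables.
ID_COLUMN = "patient_id"
GOLD_COLUMN = "gold_diagnosis"


def _parse_cell(attr: Attribute, raw: Optional[str], where: str) -> Value:
    if raw is None:
        return None
    text = raw.strip()
    if text == "":
        return None
    if attr.is_binary:
        low = text.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ValidationError(f"attribute {attr.name!r}: cannot parse {text!r} as true/false ({where})")
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"attribute {attr.name!r}: cannot parse {text!r} as a number ({where})") from None


def load_cohort(path: Union[str, Path], schema: Optional[AttributeSchema] = None) -> list[PatientRecord]:
    """Read a patient table from CSV.

    The header must name every schema attribute (order free); empty cells
    denote Missing.  A ``patient_id`` column and a ``gold_diagnosis``
    column (labels HFrEF/HFmrEF/HFpEF/NoHF) are optional.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = set(schema.names) | {ID_COLUMN, GOLD_COLUMN}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown column(s) {unknown} in {path}")
    absent = [n for n in schema.names if n not in df.columns]
    if absent:
        raise SchemaError(f"missing attribute column(s) {absent} in {path}")

    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowmap = dict(zip(df.columns, row))
        pid = rowmap.get(ID_COLUMN, "").strip() or f"row{i}"
        where = f"row {i}"
        values = {a.name: _parse_cell(a, rowmap.get(a.name), where) for a in schema}
        gold = None
        raw_gold = rowmap.get(GOLD_COLUMN, "").strip()
        if raw_gold:
            try:
                gold = Diagnosis(raw_gold)
            except ValueError:
                raise ValidationError(
                    f"unknown diagnosis label {raw_gold!r} ({where})"
                ) from None
        rec = PatientRecord(pid, values, gold)
        for name in schema.names:
            rec.values[name] = schema.check_value(name, rec.values[name], where=where)
        records.append(rec)
    return records


def _format_value(attr: Attribute, value: Value) -> str:
    if value is None:
        return ""
    if attr.is_binary:
        return "true" if value else "false"
    return format(float(value), ".10g")


def save_cohort(
    records: Sequence[PatientRecord],
    path: Union[str, Path],
    schema: Optional[AttributeSchema] = None,
) -> None:
    """Write records to CSV (inverse of :func:`load_cohort`)."""
    schema = schema or default_schema()
    cols = [ID_COLUMN, *schema.names, GOLD_COLUMN]
    rows = []
    for rec in records:
        row = {ID_COLUMN: rec.patient_id}
        for a in schema:
            row[a.name] = _format_value(a, rec.values.get(a.name))
        row[GOLD_COLUMN] = rec.gold_diagnosis.value if rec.gold_diagnosis else ""
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
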