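"""Domain types and delimited-text I/O for vital records and hospital episodes.

The real statewide files are restricted, so the package defines its own
documented CSV layouts: ISO-8601 dates, empty string as the missing token,
zip codes kept as strings (leading zeros), and multi-valued ICD code fields
serialized as a semicolon-separated sub-list with a ``system:`` prefix per
code (for example ``icd10:O24.4;icd9:648.0``).  Every reader validates
against a :class:`ColumnDictionary`; write followed by read is lossless.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

__all__ = [
    "VitalRecord",
    "HospitalEpisode",
    "ColumnSpec",
    "ColumnDictionary",
    "SchemaError",
    "RowDiagnostic",
    "ReadResult",
    "VITAL_DICTIONARY",
    "HOSPITAL_DICTIONARY",
    "read_vital_file",
    "read_hospital_file",
    "write_vital_file",
    "write_hospital_file",
    "write_linked_cohort",
    "read_linked_cohort",
]

PAYERS = ("private", "public", "self_pay", "other", "unknown")
RACE_ETH = ("amer_indian_alaska_native", "asian", "black",
            "hawaiian_pacific_islander", "hispanic", "white_nh",
            "other", "multiple", "unknown")
SEXES = ("M", "F", "unknown")
PLURALITIES = ("singleton", "twin", "multiple")
EDUCATION = ("lt12", "12", "gt12", "unknown")
RECORD_TYPES = ("PDD", "ED", "AS")
PERSON_ROLES = ("mother", "infant", "unknown")
DISCHARGE_STATUSES = ("routine", "died", "other")


class SchemaError(ValueError):
    """Raised when a file's header or structure violates its dictionary."""


@dataclass(frozen=True)
class RowDiagnostic:
    """One rejected row: where, which record, and why."""

    row: int
    record_id: str
    message: str


@dataclass
class ReadResult:
    """Parsed records plus row-level diagnostics for rejected rows."""

    records: list
    diagnostics: list[RowDiagnostic] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


@dataclass(frozen=True)
class VitalRecord:
    """One birth or fetal-death certificate row (the linkage base file).

    ``record_id`` plays the role of a state file number: unique within a
    file.  Fetal deaths carry ``infant_death=None`` (undefined) and can
    never link to an infant hospital record.  ``conditions`` holds the
    certificate-recorded condition labels (used by the hypertension and
    diabetes comparators and by the dual-source ascertainment evaluation).
    ``sibling_set_id`` is shared by all records of one delivery.
    """

    record_id: str
    year: int
    infant_dob: date
    sibling_set_id: str
    is_fetal_death: bool = False
    mother_dob: date | None = None
    hospital_id: str | None = None
    zip: str | None = None
    county: str | None = None
    payer: str = "unknown"
    race_eth: str = "unknown"
    infant_sex: str = "unknown"
    gestational_age_wk: int | None = None
    birthweight_g: int | None = None
    plurality: str = "singleton"
    birth_order: int = 1
    cesarean: bool = False
    previous_cesarean: bool = False
    infant_death: bool | None = False
    education: str = "unknown"
    mother_age_yrs: int | None = None
    conditions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.gestational_age_wk is not None and not (20 <= self.gestational_age_wk <= 44):
            raise ValueError(
                f"{self.record_id}: gestational_age_wk {self.gestational_age_wk} outside 20-44")
        if self.plurality == "singleton" and self.birth_order != 1:
            raise ValueError(f"{self.record_id}: singleton with birth_order != 1")


@dataclass(frozen=True)
class HospitalEpisode:
    """One discharge/ED/ambulatory-surgery row with ICD codes.

    ``diagnosis_codes`` and ``procedure_codes`` are ``(system, code)``
    pairs with ``system`` in {icd9, icd10}.  ``enc_ssn`` is an opaque
    encrypted-SSN token; real coverage is high for birthing people and
    low for infants, which the synthetic generator emulates.
    """

    episode_id: str
    record_type: str
    admit_date: date
    discharge_date: date
    person_role: str = "unknown"
    hospital_id: str | None = None
    patient_dob: date | None = None
    zip: str | None = None
    county: str | None = None
    payer: str = "unknown"
    race_eth: str = "unknown"
    sex: str = "unknown"
    diagnosis_codes: tuple[tuple[str, str], ...] = ()
    procedure_codes: tuple[tuple[str, str], ...] = ()
    mdc: int | None = None
    discharge_status: str = "routine"
    enc_ssn: str | None = None
    age_at_admission_yrs: int | None = None

    def __post_init__(self):
        if self.admit_date > self.discharge_date:
            raise ValueError(f"{self.episode_id}: admit_date after discharge_date")


@dataclass(frozen=True)
class ColumnSpec:
    """Type and allowed-value contract for one column."""

    name: str
    kind: str  # str | int | date | flag | cat | codes | labels
    allowed: tuple[str, ...] = ()
    required: bool = True  # value may not be the missing token


@dataclass(frozen=True)
class ColumnDictionary:
    """Ordered column contract for one file layout; missing token is ''."""

    columns: tuple[ColumnSpec, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    def check_header(self, header: Sequence[str]) -> None:
        unknown = set(header) - set(self.names)
        missing = set(self.names) - set(header)
        if unknown or missing:
            parts = []
            if unknown:
                parts.append(f"unknown columns {sorted(unknown)}")
            if missing:
                parts.append(f"missing columns {sorted(missing)}")
            raise SchemaError("; ".join(parts))


def _cat(name, allowed, required=True):
    return ColumnSpec(name, "cat", tuple(allowed), required)


VITAL_DICTIONARY = ColumnDictionary(columns=(
    ColumnSpec("record_id", "str"),
    ColumnSpec("year", "int"),
    ColumnSpec("is_fetal_death", "flag"),
    ColumnSpec("mother_dob", "date", required=False),
    ColumnSpec("infant_dob", "date"),
    ColumnSpec("hospital_id", "str", required=False),
    ColumnSpec("zip", "str", required=False),
    ColumnSpec("county", "str", required=False),
    _cat("payer", PAYERS),
    _cat("race_eth", RACE_ETH),
    _cat("infant_sex", SEXES),
    ColumnSpec("gestational_age_wk", "int", required=False),
    ColumnSpec("birthweight_g", "int", required=False),
    _cat("plurality", PLURALITIES),
    ColumnSpec("birth_order", "int"),
    ColumnSpec("cesarean", "flag"),
    ColumnSpec("previous_cesarean", "flag"),
    ColumnSpec("infant_death", "flag", required=False),
    _cat("education", EDUCATION),
    ColumnSpec("mother_age_yrs", "int", required=False),
    ColumnSpec("sibling_set_id", "str"),
    ColumnSpec("conditions", "labels", required=False),
))

HOSPITAL_DICTIONARY = ColumnDictionary(columns=(
    ColumnSpec("episode_id", "str"),
    _cat("person_role", PERSON_ROLES),
    _cat("record_type", RECORD_TYPES),
    ColumnSpec("hospital_id", "str", required=False),
    ColumnSpec("admit_date", "date"),
    ColumnSpec("discharge_date", "date"),
    ColumnSpec("patient_dob", "date", required=False),
    ColumnSpec("zip", "str", required=False),
    ColumnSpec("county", "str", required=False),
    _cat("payer", PAYERS),
    _cat("race_eth", RACE_ETH),
    _cat("sex", SEXES),
    ColumnSpec("diagnosis_codes", "codes", required=False),
    ColumnSpec("procedure_codes", "codes", required=False),
    ColumnSpec("mdc", "int", required=False),
    _cat("discharge_status", DISCHARGE_STATUSES),
    ColumnSpec("enc_ssn", "str", required=False),
    ColumnSpec("age_at_admission_yrs", "int", required=False),
))


def _parse_value(spec: ColumnSpec, raw: str):
    if raw == "":
        if spec.required:
            raise ValueError(f"column {spec.name!r}: required value missing")
        return None
    if spec.kind == "str":
        return raw
    if spec.kind == "int":
        return int(raw)
    if spec.kind == "date":
        return date.fromisoformat(raw)
    if spec.kind == "flag":
        if raw not in ("0", "1"):
            raise ValueError(f"column {spec.name!r}: flag must be 0 or 1, got {raw!r}")
        return raw == "1"
    if spec.kind == "cat":
        if raw not in spec.allowed:
            raise ValueError(f"column {spec.name!r}: {raw!r} not in {spec.allowed}")
        return raw
    if spec.kind == "codes":
        out = []
        for item in raw.split(";"):
            system, _, code = item.partition(":")
            if system not in ("icd9", "icd10") or not code:
                raise ValueError(f"column {spec.name!r}: bad code item {item!r}")
            out.append((system, code))
        return tuple(out)
    if spec.kind == "labels":
        return frozenset(raw.split(";"))
    raise AssertionError(spec.kind)


def _format_value(spec: ColumnSpec, value) -> str:
    if value is None:
        return ""
    if spec.kind == "flag":
        return "1" if value else "0"
    if spec.kind == "codes":
        return ";".join(f"{system}:{code}" for system, code in value)
    if spec.kind == "labels":
        return ";".join(sorted(value))
    return str(value)


def _read_rows(path, dictionary: ColumnDictionary):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file (no header)")
        dictionary.check_header(reader.fieldnames)
        yield from enumerate(reader, start=2)  # 1-based, after header


def _read_file(path, dictionary, factory, id_column, strict):
    records, diagnostics, seen = [], [], set()
    for lineno, row in _read_rows(path, dictionary):
        rid = row.get(id_column, "")
        try:
            parsed = {spec.name: _parse_value(spec, row[spec.name])
                      for spec in dictionary.columns}
            if parsed[id_column] in seen:
                raise ValueError(f"duplicate {id_column} {parsed[id_column]!r}")
            record = factory(parsed)
            seen.add(parsed[id_column])
            records.append(record)
        except (ValueError, KeyError) as exc:
            diag = RowDiagnostic(row=lineno, record_id=rid, message=str(exc))
            if strict:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
            diagnostics.append(diag)
    return ReadResult(records=records, diagnostics=diagnostics)


def _vital_factory(parsed: dict) -> VitalRecord:
    parsed = dict(parsed)
    if parsed["conditions"] is None:
        parsed["conditions"] = frozenset()
    return VitalRecord(**parsed)


def _hospital_factory(parsed: dict) -> HospitalEpisode:
    parsed = dict(parsed)
    for key in ("diagnosis_codes", "procedure_codes"):
        if parsed[key] is None:
            parsed[key] = ()
    return HospitalEpisode(**parsed)


def read_vital_file(path, dictionary: ColumnDictionary = VITAL_DICTIONARY,
                    strict: bool = False) -> ReadResult:
    """Read a vital-records CSV; bad rows become diagnostics unless strict."""
    return _read_file(path, dictionary, _vital_factory, "record_id", strict)


def read_hospital_file(path, dictionary: ColumnDictionary = HOSPITAL_DICTIONARY,
                       strict: bool = False) -> ReadResult:
    """Read a hospital-episode CSV; bad rows become diagnostics unless strict."""
    return _read_file(path, dictionary, _hospital_factory, "episode_id", strict)


def _write_file(path, dictionary, records, getter):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(dictionary.names)
        for record in records:
            writer.writerow(_format_value(spec, getter(record, spec.name))
                            for spec in dictionary.columns)


def write_vital_file(records: Iterable[VitalRecord], path) -> None:
    _write_file(path, VITAL_DICTIONARY, records, getattr)


def write_hospital_file(records: Iterable[HospitalEpisode], path) -> None:
    _write_file(path, HOSPITAL_DICTIONARY, records, getattr)


#: Columns appended to the vital layout in the linked-cohort output.
LINK_COLUMNS = ColumnDictionary(columns=VITAL_DICTIONARY.columns + (
    ColumnSpec("mother_episode_id", "str", required=False),
    ColumnSpec("mother_pass", "str", required=False),
    ColumnSpec("mother_score", "int", required=False),
    ColumnSpec("mother_tiebreak", "flag", required=False),
    ColumnSpec("infant_episode_id", "str", required=False),
    ColumnSpec("infant_pass", "str", required=False),
    ColumnSpec("infant_score", "int", required=False),
    ColumnSpec("infant_tiebreak", "flag", required=False),
))


def write_linked_cohort(result, vitals: Sequence[VitalRecord], path) -> None:
    """Write one row per vital record with its linked episode ids and scores.

    ``result`` is a :class:`vitalink.engine.LinkageResult`; unlinked sides
    leave their link columns empty.  The output is re-readable with
    :func:`read_linked_cohort`.
    """
    def getter(record, name):
        if hasattr(record, name):
            return getattr(record, name)
        side, _, col = name.partition("_")
        a = (result.mother if side == "mother" else result.infant).get(record.record_id)
        if a is None:
            return None
        return {"episode": a.episode_id, "pass": a.pass_label,
                "score": a.score, "tiebreak": a.tiebreak_used}[col.split("_")[0]]

    _write_file(path, LINK_COLUMNS, vitals, getter)


def read_linked_cohort(path, strict: bool = False) -> ReadResult:
    """Read a linked-cohort CSV back into plain row dictionaries."""
    records, diagnostics = [], []
    for lineno, row in _read_rows(path, LINK_COLUMNS):
        try:
            records.append({spec.name: _parse_value(spec, row[spec.name])
                            for spec in LINK_COLUMNS.columns})
        except (ValueError, KeyError) as exc:
            if strict:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
            diagnostics.append(RowDiagnostic(lineno, row.get("record_id", ""), str(exc)))
    return ReadResult(records=records, diagnostics=diagnostics)
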