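"""ICD-9/ICD-10 code handling and clinical-indicator derivation.

Hospital discharge abstracts carry diagnoses and procedures as ICD codes;
the linkage comparators and the dual-source ascertainment evaluation both
work from a small number of binary or banded clinical indicators derived
from those codes (gestational-age band, birthweight band, delivery mode,
plurality, maternal comorbidities, and so on).  Each indicator is defined
by a :class:`CodeSet` of code prefixes; matching is prefix-based on
normalized codes, so "O24.4" on a record matches the diabetes prefix
"O24".

The default code sets ship as a packaged YAML file
(``vitalink/data/code_sets.yaml``) and can be overridden for sensitivity
analyses via :func:`load_code_sets`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "CodeSet",
    "BandSpec",
    "ClinicalIndicators",
    "CodeSetLibrary",
    "normalize_code",
    "load_code_sets",
    "default_code_sets",
    "derive_indicators",
    "is_pregnancy_or_birth_record",
    "ASCERTAINMENT_INDICATORS",
]

#: Table-4-style ascertainment indicator labels (order is presentation order).
ASCERTAINMENT_INDICATORS = (
    "gestational_diabetes",
    "preexisting_diabetes",
    "prepregnancy_hypertension",
    "gestational_hypertension",
    "eclampsia",
    "placental_abruption",
    "chorioamnionitis",
    "neural_tube_defect",
    "gastroschisis_omphalocele",
    "cleft_lip_palate",
    "major_heart_defect",
)


def normalize_code(code: str, system: str) -> str:
    """Normalize a raw ICD code: strip whitespace and dots, uppercase.

    ``system`` must be ``"icd9"`` or ``"icd10"`` and is validated but not
    embedded in the returned string (codes travel as ``(system, code)``
    pairs throughout the package).

    Raises
    ------
    ValueError
        If ``code`` is empty/blank or ``system`` is unknown.
    """
    if system not in ("icd9", "icd10"):
        raise ValueError(f"unknown code system: {system!r}")
    cleaned = code.strip().upper().replace(".", "")
    if not cleaned:
        raise ValueError("empty ICD code")
    return cleaned


@dataclass(frozen=True)
class CodeSet:
    """One indicator label with its ICD-9 and ICD-10 prefix sets.

    ``procedure`` prefixes (where present) are matched against procedure
    codes; plain prefixes are matched against diagnosis codes.
    """

    name: str
    icd9_prefixes: tuple[str, ...] = ()
    icd10_prefixes: tuple[str, ...] = ()
    icd9_proc_prefixes: tuple[str, ...] = ()
    icd10_proc_prefixes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for group in (self.icd9_prefixes, self.icd10_prefixes,
                      self.icd9_proc_prefixes, self.icd10_proc_prefixes):
            for p in group:
                if not p:
                    raise ValueError(f"code set {self.name!r}: empty prefix")

    def matches(self, diagnosis_codes: Iterable[tuple[str, str]],
                procedure_codes: Iterable[tuple[str, str]] = ()) -> bool:
        """True if any code prefix-matches this set (after normalization)."""
        for system, code in diagnosis_codes:
            norm = normalize_code(code, system)
            prefixes = self.icd9_prefixes if system == "icd9" else self.icd10_prefixes
            if any(norm.startswith(_norm_prefix(p)) for p in prefixes):
                return True
        for system, code in procedure_codes:
            norm = normalize_code(code, system)
            prefixes = (self.icd9_proc_prefixes if system == "icd9"
                        else self.icd10_proc_prefixes)
            if any(norm.startswith(_norm_prefix(p)) for p in prefixes):
                return True
        return False


def _norm_prefix(prefix: str) -> str:
    return prefix.strip().upper().replace(".", "")


@dataclass(frozen=True)
class BandSpec:
    """A mutually exclusive banded indicator (one CodeSet per level).

    ``priority`` resolves conflicts: when codes on one episode imply more
    than one level, the earliest listed level wins.  The shipped defaults
    put the extreme, high-scoring levels first ("worst first"), mirroring
    clinical coding conventions.
    """

    name: str
    levels: Mapping[str, CodeSet]
    priority: tuple[str, ...]

    def classify(self, diagnosis_codes, procedure_codes=()) -> str:
        hits = [lvl for lvl in self.priority
                if self.levels[lvl].matches(diagnosis_codes, procedure_codes)]
        return hits[0] if hits else "unknown"


@dataclass(frozen=True)
class CodeSetLibrary:
    """All band and flag code sets used by scoring and evaluation."""

    bands: Mapping[str, BandSpec]
    flags: Mapping[str, CodeSet]
    ascertainment: Mapping[str, CodeSet]


@dataclass(frozen=True)
class ClinicalIndicators:
    """Indicators derived from one hospital episode's codes.

    Bands default to ``"unknown"`` and flags to absent when no code
    matches; ``conditions`` holds every true flag label (comparator flags
    and ascertainment flags alike).
    """

    ga_band: str = "unknown"
    birthweight_band: str = "unknown"
    plurality: str = "unknown"
    infant_died: bool = False
    conditions: frozenset[str] = field(default_factory=frozenset)

    def has(self, label: str) -> bool:
        return label in self.conditions

    @property
    def cesarean(self) -> bool:
        return "cesarean" in self.conditions

    @property
    def previous_cesarean(self) -> bool:
        return "previous_cesarean" in self.conditions

    @property
    def sga_lga(self) -> bool:
        return "sga_lga" in self.conditions

    @property
    def hypertension_preg(self) -> bool:
        return "hypertension_preg" in self.conditions

    @property
    def diabetes_any(self) -> bool:
        return "diabetes_any" in self.conditions


def _parse_code_set(name: str, block: Mapping) -> CodeSet:
    return CodeSet(
        name=name,
        icd9_prefixes=tuple(block.get("icd9", ()) or ()),
        icd10_prefixes=tuple(block.get("icd10", ()) or ()),
        icd9_proc_prefixes=tuple(block.get("icd9_proc", ()) or ()),
        icd10_proc_prefixes=tuple(block.get("icd10_proc", ()) or ()),
    )


def load_code_sets(source) -> CodeSetLibrary:
    """Load a :class:`CodeSetLibrary` from a YAML path or mapping."""
    if isinstance(source, Mapping):
        raw = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    bands = {}
    for band_name, band_block in raw.get("bands", {}).items():
        levels = {lvl: _parse_code_set(f"{band_name}:{lvl}", blk)
                  for lvl, blk in band_block["levels"].items()}
        priority = tuple(band_block["priority"])
        if set(priority) != set(levels):
            raise ValueError(f"band {band_name!r}: priority must list every level")
        bands[band_name] = BandSpec(band_name, levels, priority)
    flags = {n: _parse_code_set(n, b) for n, b in raw.get("flags", {}).items()}
    asc = {n: _parse_code_set(n, b) for n, b in raw.get("ascertainment", {}).items()}
    return CodeSetLibrary(bands=bands, flags=flags, ascertainment=asc)


@lru_cache(maxsize=1)
def default_code_sets() -> CodeSetLibrary:
    """The packaged default code sets."""
    text = resources.files("vitalink.data").joinpath("code_sets.yaml").read_text()
    return load_code_sets(yaml.safe_load(text))


def derive_indicators(episode, code_sets: CodeSetLibrary | None = None) -> ClinicalIndicators:
    """Map an episode's ICD codes (and discharge status) to indicators.

    Both ICD-9 and ICD-10 columns are matched on every episode regardless
    of the discharge date: the coding-system transition falls inside the
    study window and dual matching against tagged prefix sets is harmless.
    Unrecognized codes are ignored.
    """
    lib = code_sets or default_code_sets()
    dx = episode.diagnosis_codes
    px = episode.procedure_codes
    conditions = set()
    for name, cs in lib.flags.items():
        if cs.matches(dx, px):
            conditions.add(name)
    for name, cs in lib.ascertainment.items():
        if cs.matches(dx, px):
            conditions.add(name)
    return ClinicalIndicators(
        ga_band=lib.bands["ga_band"].classify(dx, px),
        birthweight_band=lib.bands["birthweight_band"].classify(dx, px),
        plurality=lib.bands["plurality"].classify(dx, px),
        infant_died=(episode.discharge_status == "died"),
        conditions=frozenset(conditions),
    )


# Pregnancy/birth restriction applied before the infant linkage.
_ICD10_PREG_PREFIXES = ("O1", "O2", "O3", "O4", "O6", "O7", "O8", "O9")


def is_pregnancy_or_birth_record(episode) -> bool:
    """True when an episode indicates a pregnancy, delivery, or newborn stay.

    Qualifying evidence: major diagnostic category 14; an ICD-9 diagnosis
    V23 or in 640-679; an ICD-10 diagnosis starting O1/O2/O3/O4/O6/O7/O8/O9;
    or newborn-admission evidence (ICD-10 Z38*, ICD-9 V30-V39, or age 0 at
    admission), without which infant birth stays would be filtered out.
    """
    if episode.mdc == 14:
        return True
    if episode.age_at_admission_yrs == 0:
        return True
    for system, code in episode.diagnosis_codes:
        norm = normalize_code(code, system)
        if system == "icd9":
            if norm.startswith("V23"):
                return True
            if len(norm) >= 2 and norm[:2] == "V3" and len(norm) >= 3 and norm[2].isdigit():
                return True  # V30-V39 newborn admission
            if norm[:3].isdigit() and 640 <= int(norm[:3]) <= 679:
                return True
        else:
            if norm.startswith(_ICD10_PREG_PREFIXES):
                return True
            if norm.startswith("Z38"):
                return True
    return False
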