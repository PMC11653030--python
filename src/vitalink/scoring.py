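"""Per-variable comparators and the additive link score.

A candidate (vital record, hospital episode) pair is scored by comparing
eighteen variables; each variable contributes a fixed number of points at
the concordance level it reaches, and the link score is the sum.  Dates
compare at four levels (exact, month/day transposed, year-differs, none);
banded clinical variables (gestational age, birthweight, plurality) score
by band, with the extreme bands worth more because agreement there is far
less likely by chance; plain categorical and flag variables score at a
single "exact" level.  A variable missing on either side contributes 0 and
cannot serve as required evidence.

The maternal link additionally tracks the required-variable rule: the
birthing person's date of birth, the infant's date of birth, and the
hospital must all link (the mother's date of birth may be satisfied by a
month/day transposition or a differing year — a relaxation that confers
eligibility, not points beyond the printed 5), and at least one other
variable must link.  The infant-side score uses the reduced variable set
available on newborn records and records sex concordance as a hard flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from functools import lru_cache
from importlib import resources
from typing import Mapping

import yaml

from .icd import ClinicalIndicators

__all__ = [
    "ComparatorSpec",
    "ScoreBreakdown",
    "compare_date",
    "score_mother_pair",
    "score_infant_pair",
    "mother_levels",
    "infant_levels",
    "breakdown_from_levels",
    "default_comparator_spec",
    "vital_ga_band",
    "vital_birthweight_band",
    "vital_sga_lga",
    "MOTHER_VARIABLES",
    "INFANT_VARIABLES",
    "REQUIRED_TRIPLE",
]

MOTHER_VARIABLES = (
    "mother_dob", "hospital", "infant_dob", "zip", "ga", "sex", "payer",
    "race", "ethnicity", "county", "infant_death", "cesarean",
    "previous_cesarean", "birthweight", "sga_lga", "hypertension",
    "diabetes", "plurality",
)
# Newborn abstracts carry no maternal date of birth and no maternal-history
# comparators (previous cesarean, hypertension, diabetes).
INFANT_VARIABLES = tuple(v for v in MOTHER_VARIABLES if v not in
                         ("mother_dob", "previous_cesarean", "hypertension", "diabetes"))
REQUIRED_TRIPLE = ("mother_dob", "infant_dob", "hospital")

# Race categories earning the extra +5 on concordance; a White match earns
# +2; other categories earn the base 5 only.
_MINORITY_RACES = frozenset({"amer_indian_alaska_native", "asian", "black",
                             "hawaiian_pacific_islander", "other"})


@dataclass(frozen=True)
class ComparatorSpec:
    """Point table: variable -> {concordance level -> points}."""

    points: Mapping[str, Mapping[str, int]]

    def __post_init__(self):
        for var, levels in self.points.items():
            for lvl, pts in levels.items():
                if not isinstance(pts, int) or pts < 0:
                    raise ValueError(f"{var}:{lvl}: points must be nonnegative integers")

    def value(self, variable: str, level: str) -> int:
        return self.points[variable].get(level, 0)

    def max_points(self, variable: str) -> int:
        return max(self.points[variable].values())

    def total_max(self, variables=MOTHER_VARIABLES) -> int:
        """Sum of per-variable maxima (148 for the shipped maternal table)."""
        return sum(self.max_points(v) for v in variables)

    @classmethod
    def from_yaml(cls, source) -> "ComparatorSpec":
        if isinstance(source, Mapping):
            raw = source
        else:
            with open(source, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        return cls(points={v: dict(levels) for v, levels in raw.items()})


@lru_cache(maxsize=1)
def default_comparator_spec() -> ComparatorSpec:
    text = resources.files("vitalink.data").joinpath("score_table.yaml").read_text()
    return ComparatorSpec.from_yaml(yaml.safe_load(text))


def compare_date(a: date | None, b: date | None) -> str:
    """Compare two dates: exact, transposed, year_differs, or none.

    ``transposed`` means swapping month and day of one date yields the
    other (only possible when month != day); ``year_differs`` means month
    and day agree but the year does not.  Symmetric in its arguments.
    Missing dates compare as ``none``.
    """
    if a is None or b is None:
        return "none"
    if a == b:
        return "exact"
    if (a.year == b.year and a.month == b.day and a.day == b.month
            and a.month != a.day):
        return "transposed"
    if a.month == b.month and a.day == b.day and a.year != b.year:
        return "year_differs"
    return "none"


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-variable contributions plus the total link score.

    ``contributions`` maps each non-missing concordant variable to its
    (level, points) pair; variables at level ``none`` or missing on either
    side are absent.  ``total`` always equals the sum of contributions.
    """

    contributions: Mapping[str, tuple[str, int]]
    total: int
    side: str  # "mother" | "infant"

    @property
    def mother_dob_linked(self) -> bool:
        lvl = self.contributions.get("mother_dob", ("none", 0))[0]
        return lvl in ("exact", "transposed", "year_differs")

    @property
    def infant_dob_linked(self) -> bool:
        lvl = self.contributions.get("infant_dob", ("none", 0))[0]
        return lvl in ("exact", "transposed")

    @property
    def hospital_linked(self) -> bool:
        return "hospital" in self.contributions

    @property
    def dob_relaxation_used(self) -> bool:
        m = self.contributions.get("mother_dob", ("none", 0))[0]
        i = self.contributions.get("infant_dob", ("none", 0))[0]
        return m in ("transposed", "year_differs") or i == "transposed"

    @property
    def other_variable_linked(self) -> bool:
        """At least one variable beyond the required triple contributed points."""
        return any(pts > 0 for var, (lvl, pts) in self.contributions.items()
                   if var not in REQUIRED_TRIPLE)

    @property
    def sex_concordant(self) -> bool:
        return "sex" in self.contributions


def breakdown_from_levels(levels: Mapping[str, str],
                          spec: ComparatorSpec | None = None,
                          side: str = "mother") -> ScoreBreakdown:
    """Build a :class:`ScoreBreakdown` from variable -> level assignments.

    Levels of ``"none"`` are dropped; ``year_differs`` is kept at 0 points
    so the eligibility relaxation remains visible in the breakdown.
    """
    spec = spec or default_comparator_spec()
    contributions = {}
    total = 0
    for var, lvl in levels.items():
        if lvl == "none":
            continue
        pts = spec.value(var, lvl)
        contributions[var] = (lvl, pts)
        total += pts
    return ScoreBreakdown(contributions=contributions, total=total, side=side)


def vital_ga_band(v) -> str:
    """Scoring band for a vital record's gestational age in weeks."""
    wk = v.gestational_age_wk
    if wk is None:
        return "unknown"
    if wk < 29:
        return "lt29"
    if wk < 37:
        return "29to36"
    if wk <= 42:
        return "37to42"
    return "gt42"


def vital_birthweight_band(v) -> str:
    g = v.birthweight_g
    if g is None:
        return "unknown"
    if g < 2500:
        return "lt2500"
    if g < 4500:
        return "2500to4499"
    return "ge4500"


def vital_sga_lga(v) -> bool:
    """Certificate-side small/large-for-gestational-age proxy.

    Birth certificates carry no SGA/LGA field; the proxy flags term
    (>=37 wk) births under 2500 g and any birth of 4500 g or more.
    """
    if v.birthweight_g is None:
        return False
    if v.birthweight_g >= 4500:
        return True
    return (v.gestational_age_wk is not None and v.gestational_age_wk >= 37
            and v.birthweight_g < 2500)


def _exact(a, b, missing=("unknown", None)) -> str:
    if a in missing or b in missing:
        return "none"
    return "exact" if a == b else "none"


def _flag_level(vital_flag: bool | None, episode_flag: bool) -> str:
    # Flag comparators score on positive concordance only: an absent code
    # on the hospital side is no evidence of absence.
    return "exact" if (vital_flag is True and episode_flag) else "none"


def _race_level(a: str, b: str) -> str:
    if a == "unknown" or b == "unknown" or a != b:
        return "none"
    if a in _MINORITY_RACES:
        return "minority"
    if a == "white_nh":
        return "white"
    return "match"  # hispanic, multiple: base points, no printed bonus


def _ethnicity_level(a: str, b: str) -> str:
    if a == "unknown" or b == "unknown":
        return "none"
    return "exact" if (a == "hispanic") == (b == "hispanic") else "none"


def _band_level(a: str, b: str) -> str:
    if a == "unknown" or b == "unknown" or a != b:
        return "none"
    return a


def _plurality_level(a: str, b: str) -> str:
    if a == "unknown" or b == "unknown":
        return "none"
    if a == "singleton" and b == "singleton":
        return "singleton"
    if a in ("twin", "multiple") and b in ("twin", "multiple"):
        return "multi"
    return "none"


def _shared_levels(v, e, ind: ClinicalIndicators) -> dict[str, str]:
    return {
        "hospital": _exact(v.hospital_id, e.hospital_id),
        "zip": _exact(v.zip, e.zip),
        "ga": _band_level(vital_ga_band(v), ind.ga_band),
        "sex": _exact(v.infant_sex, e.sex),
        "payer": _exact(v.payer, e.payer),
        "race": _race_level(v.race_eth, e.race_eth),
        "ethnicity": _ethnicity_level(v.race_eth, e.race_eth),
        "county": _exact(v.county, e.county),
        "infant_death": _flag_level(v.infant_death, ind.infant_died),
        "cesarean": _flag_level(v.cesarean, ind.cesarean),
        "birthweight": _band_level(vital_birthweight_band(v), ind.birthweight_band),
        "sga_lga": _flag_level(vital_sga_lga(v), ind.sga_lga),
        "plurality": _plurality_level(v.plurality, ind.plurality),
    }


def mother_levels(v, e, ind: ClinicalIndicators) -> dict[str, str]:
    """Concordance levels for a vital record against a maternal episode.

    Maternal discharge abstracts carry no infant date-of-birth field, so
    the infant's date of birth counts as exactly linked when it falls
    inside the episode's admission window; transposition checking applies
    only to the mother's own date of birth.
    """
    levels = _shared_levels(v, e, ind)
    levels["mother_dob"] = compare_date(v.mother_dob, e.patient_dob)
    levels["infant_dob"] = ("exact" if e.admit_date <= v.infant_dob <= e.discharge_date
                            else "none")
    levels["previous_cesarean"] = _flag_level(v.previous_cesarean, ind.previous_cesarean)
    levels["hypertension"] = _flag_level("hypertension_preg" in v.conditions,
                                         ind.hypertension_preg)
    levels["diabetes"] = _flag_level("diabetes_any" in v.conditions, ind.diabetes_any)
    return levels


def infant_levels(v, e, ind: ClinicalIndicators) -> dict[str, str]:
    """Concordance levels for a vital record against an infant episode."""
    levels = _shared_levels(v, e, ind)
    levels["infant_dob"] = compare_date(v.infant_dob, e.patient_dob)
    return levels


def score_mother_pair(v, e, ind: ClinicalIndicators,
                      spec: ComparatorSpec | None = None) -> ScoreBreakdown:
    """Score a candidate maternal link over the full comparator table."""
    return breakdown_from_levels(mother_levels(v, e, ind), spec, side="mother")


def score_infant_pair(v, e, ind: ClinicalIndicators,
                      spec: ComparatorSpec | None = None) -> ScoreBreakdown:
    """Score a candidate infant link over the newborn comparator subset."""
    return breakdown_from_levels(infant_levels(v, e, ind), spec, side="infant")
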