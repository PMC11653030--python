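"""Linkage-quality and data-quality evaluation surfaces.

Four views are computed over a linkage result: stratified linkage-rate
tables (overall and by year, demographics, and pregnancy outcomes, with
fetal deaths excluded from infant-side denominators); linked-versus-
unlinked characteristic distributions (the selection-bias diagnostic);
dual-source condition ascertainment among fully linked records
(certificate only, hospital only, and the union of both sources); and an
outcome-prevalence contrast between the full certificate population and
the linked subset.  On synthetic data, where a truth table exists, the
two linkage error types — missed links and false links — are quantified
as recall and precision.

Percentages are reported to two decimals with round-half-up; counts are
never rounded; undefined ratios (zero denominators) surface as ``None``,
never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .icd import ASCERTAINMENT_INDICATORS, derive_indicators
from .records import HospitalEpisode, VitalRecord

__all__ = [
    "pct",
    "LinkageMetrics",
    "AscertainmentRow",
    "linkage_rates",
    "compare_linked_unlinked",
    "ascertainment_union",
    "prevalence_contrast",
    "truth_metrics",
    "DEFAULT_STRATA",
]


def pct(numerator: int, denominator: int) -> float | None:
    """Percentage to 2 decimals, round-half-up; None when undefined."""
    if denominator == 0:
        return None
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# Stratification variables of the linkage-rate table.
DEFAULT_STRATA = ("year", "age_band", "payer", "race_eth", "education",
                  "ga_stratum", "plurality", "infant_death")

_GA_STRATA = (("20-27", 20, 27), ("28-31", 28, 31), ("32-36", 32, 36),
              ("37-42", 37, 42), ("43-44", 43, 44))


def _stratum_value(v: VitalRecord, name: str) -> str:
    if name == "year":
        return str(v.year)
    if name == "age_band":
        a = v.mother_age_yrs
        if a is None:
            return "missing"
        return "lt18" if a < 18 else ("18to34" if a <= 34 else "gt34")
    if name == "ga_stratum":
        wk = v.gestational_age_wk
        if wk is None:
            return "missing"
        for label, lo, hi in _GA_STRATA:
            if lo <= wk <= hi:
                return label
        return "missing"
    if name == "infant_death":
        return "yes" if v.infant_death else "no"
    if name in ("payer", "race_eth", "education", "plurality"):
        return getattr(v, name)
    raise ValueError(f"unknown stratum variable {name!r}")


@dataclass
class LinkageMetrics:
    """Counts and percentage linkage rates, overall and per stratum.

    Rates recompute exactly from the counts; truth-based precision /
    recall are filled only for synthetic runs.
    """

    n_total: int
    n_linked_mother: int
    n_linked_infant: int
    n_linked_both: int
    rate_mother: float | None
    rate_infant: float | None
    rate_both: float | None
    n_fetal_deaths: int = 0
    n_fetal_linked_mother: int = 0
    rate_fetal_mother: float | None = None
    strata: dict[str, dict[str, dict]] = field(default_factory=dict)
    precision: dict | None = None
    recall: dict | None = None

    @classmethod
    def from_counts(cls, n_total: int, n_linked_mother: int,
                    n_linked_infant: int, n_linked_both: int) -> "LinkageMetrics":
        if n_linked_both > min(n_linked_mother, n_linked_infant):
            raise ValueError("n_linked_both exceeds a single-side count")
        return cls(n_total=n_total, n_linked_mother=n_linked_mother,
                   n_linked_infant=n_linked_infant, n_linked_both=n_linked_both,
                   rate_mother=pct(n_linked_mother, n_total),
                   rate_infant=pct(n_linked_infant, n_total),
                   rate_both=pct(n_linked_both, n_total))

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_linked_mother": self.n_linked_mother,
            "n_linked_infant": self.n_linked_infant,
            "n_linked_both": self.n_linked_both,
            "rate_mother": self.rate_mother,
            "rate_infant": self.rate_infant,
            "rate_both": self.rate_both,
            "n_fetal_deaths": self.n_fetal_deaths,
            "n_fetal_linked_mother": self.n_fetal_linked_mother,
            "rate_fetal_mother": self.rate_fetal_mother,
            "strata": self.strata,
            "precision": self.precision,
            "recall": self.recall,
        }


def linkage_rates(result, vitals: Sequence[VitalRecord],
                  strata: Iterable[str] = DEFAULT_STRATA) -> LinkageMetrics:
    """Overall and stratified linkage rates.

    Denominators are live births; fetal deaths are tallied separately and
    only on the maternal side (no infant record exists to link).
    """
    live = [v for v in vitals if not v.is_fetal_death]
    fetal = [v for v in vitals if v.is_fetal_death]
    linked_m = {rid for rid in result.mother}
    linked_i = {rid for rid in result.infant}

    def counts(records):
        n = len(records)
        m = sum(1 for v in records if v.record_id in linked_m)
        i = sum(1 for v in records if v.record_id in linked_i)
        b = sum(1 for v in records
                if v.record_id in linked_m and v.record_id in linked_i)
        return n, m, i, b

    n, m, i, b = counts(live)
    metrics = LinkageMetrics.from_counts(n, m, i, b)
    metrics.n_fetal_deaths = len(fetal)
    metrics.n_fetal_linked_mother = sum(1 for v in fetal if v.record_id in linked_m)
    metrics.rate_fetal_mother = pct(metrics.n_fetal_linked_mother, len(fetal))
    for name in strata:
        groups: dict[str, list[VitalRecord]] = {}
        for v in live:
            groups.setdefault(_stratum_value(v, name), []).append(v)
        table = {}
        for value in sorted(groups):
            sn, sm, si, sb = counts(groups[value])
            table[value] = {"n": sn, "n_mother": sm, "n_infant": si, "n_both": sb,
                            "rate_mother": pct(sm, sn), "rate_infant": pct(si, sn),
                            "rate_both": pct(sb, sn)}
        metrics.strata[name] = table
    return metrics


def compare_linked_unlinked(result, vitals: Sequence[VitalRecord],
                            characteristics: Iterable[str] = DEFAULT_STRATA
                            ) -> dict:
    """Characteristic distributions within linked and unlinked subsets.

    Returned as ``table[side][characteristic][value] -> {linked: {n, pct},
    unlinked: {n, pct}}``; column percentages within one characteristic
    sum to 100 up to rounding.  Empty subsets keep explicit zero
    denominators with ``None`` percentages.
    """
    live = [v for v in vitals if not v.is_fetal_death]
    out: dict = {}
    for side, linked_ids in (("mother", set(result.mother)),
                             ("infant", set(result.infant))):
        linked = [v for v in live if v.record_id in linked_ids]
        unlinked = [v for v in live if v.record_id not in linked_ids]
        side_table: dict = {"_n_linked": len(linked), "_n_unlinked": len(unlinked)}
        for name in characteristics:
            values = sorted({_stratum_value(v, name) for v in live})
            side_table[name] = {}
            for value in values:
                nl = sum(1 for v in linked if _stratum_value(v, name) == value)
                nu = sum(1 for v in unlinked if _stratum_value(v, name) == value)
                side_table[name][value] = {
                    "linked": {"n": nl, "pct": pct(nl, len(linked))},
                    "unlinked": {"n": nu, "pct": pct(nu, len(unlinked))},
                }
        out[side] = side_table
    return out


@dataclass(frozen=True)
class AscertainmentRow:
    """Dual-source ascertainment of one condition among fully linked records.

    Invariant: max(single source) <= union <= sum of sources.
    """

    indicator: str
    n_linked: int
    count_vs: int
    count_hospital: int
    count_union: int
    pct_vs: float | None
    pct_hospital: float | None
    pct_union: float | None

    @classmethod
    def from_counts(cls, indicator: str, n_linked: int, count_vs: int,
                    count_hospital: int, count_union: int) -> "AscertainmentRow":
        if count_union < max(count_vs, count_hospital) or count_union > count_vs + count_hospital:
            raise ValueError("union count outside [max(sources), sum(sources)]")
        return cls(indicator=indicator, n_linked=n_linked, count_vs=count_vs,
                   count_hospital=count_hospital, count_union=count_union,
                   pct_vs=pct(count_vs, n_linked),
                   pct_hospital=pct(count_hospital, n_linked),
                   pct_union=pct(count_union, n_linked))


def ascertainment_union(result, vitals: Sequence[VitalRecord],
                        episodes: Sequence[HospitalEpisode],
                        indicator: str,
                        code_sets=None) -> AscertainmentRow:
    """Count one condition per source among records linked on both sides.

    The certificate source is the record's condition labels (or the
    infant-death field); the hospital source is the indicator derived from
    the ICD codes of the record's linked maternal and infant episodes (or
    a died discharge status for infant death).
    """
    known = set(ASCERTAINMENT_INDICATORS) | {"infant_death"}
    if indicator not in known:
        raise ValueError(f"unknown ascertainment indicator {indicator!r}")
    eps = {e.episode_id: e for e in episodes}
    ind_cache: dict[str, frozenset] = {}

    def hospital_positive(v: VitalRecord) -> bool:
        for a in (result.mother.get(v.record_id), result.infant.get(v.record_id)):
            e = eps.get(a.episode_id) if a else None
            if e is None:
                continue
            if indicator == "infant_death":
                if e.person_role != "mother" and e.discharge_status == "died":
                    return True
                continue
            if e.episode_id not in ind_cache:
                ind_cache[e.episode_id] = derive_indicators(e, code_sets).conditions
            if indicator in ind_cache[e.episode_id]:
                return True
        return False

    linked = [v for v in vitals if not v.is_fetal_death
              and v.record_id in result.mother and v.record_id in result.infant]
    count_vs = count_hospital = count_union = 0
    for v in linked:
        vs = (bool(v.infant_death) if indicator == "infant_death"
              else indicator in v.conditions)
        hc = hospital_positive(v)
        count_vs += vs
        count_hospital += hc
        count_union += vs or hc
    return AscertainmentRow.from_counts(indicator, len(linked), count_vs,
                                        count_hospital, count_union)


def prevalence_contrast(result, vitals: Sequence[VitalRecord],
                        strata: str = "race_eth") -> dict:
    """Preterm-birth prevalence: full certificate population vs linked subset.

    Preterm means 20 to <37 completed weeks among live births; the linked
    subset is records linked on both sides.  Rows are overall plus one per
    stratum value.
    """
    live = [v for v in vitals if not v.is_fetal_death]
    linked = [v for v in live
              if v.record_id in result.mother and v.record_id in result.infant]

    def preterm(v: VitalRecord) -> bool:
        return v.gestational_age_wk is not None and 20 <= v.gestational_age_wk < 37

    def row(pop, sub):
        return {"population_n": len(pop), "population_preterm": sum(map(preterm, pop)),
                "population_pct": pct(sum(map(preterm, pop)), len(pop)),
                "linked_n": len(sub), "linked_preterm": sum(map(preterm, sub)),
                "linked_pct": pct(sum(map(preterm, sub)), len(sub))}

    out = {"overall": row(live, linked)}
    for value in sorted({getattr(v, strata) for v in live}):
        out[value] = row([v for v in live if getattr(v, strata) == value],
                         [v for v in linked if getattr(v, strata) == value])
    return out


def truth_metrics(result, truth) -> dict:
    """Precision/recall/F1 per side against a simulation truth table.

    A maternal link is correct when it hits the true maternal episode; an
    infant link is correct when it hits any episode in the record's
    exchangeable set (field-identical multiples cannot be told apart by
    any algorithm, so either assignment counts).  Precision is correct
    links over links made; recall is correct links over truly linkable
    records; both are ``None`` when their denominator is zero.

    Raises ``ValueError`` when the result refers to records absent from
    the truth table.
    """
    out = {}
    for side, assignments in (("mother", result.mother), ("infant", result.infant)):
        true_map = truth.mother_episode if side == "mother" else truth.infant_episode
        unknown = set(assignments) - set(true_map)
        if unknown:
            raise ValueError(f"{side}: result ids missing from truth: {sorted(unknown)[:5]}")
        correct = 0
        for rid, a in assignments.items():
            if side == "infant":
                ok_set = truth.infant_exchangeable.get(rid) or (
                    {true_map[rid]} if true_map[rid] else set())
                correct += a.episode_id in ok_set
            else:
                correct += a.episode_id == true_map[rid]
        made = len(assignments)
        linkable = sum(1 for eid in true_map.values() if eid is not None)
        precision = None if made == 0 else correct / made
        recall = None if linkable == 0 else correct / linkable
        f1 = (None if not precision or not recall or precision + recall == 0
              else 2 * precision * recall / (precision + recall))
        out[side] = {"n_links": made, "n_linkable": linkable, "n_correct": correct,
                     "precision": precision, "recall": recall, "f1": f1}
    return out
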