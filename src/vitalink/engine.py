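"""Blocking, acceptance, score-based selection, and multi-pass orchestration.

The linkage runs in two stages per pass: a blocking stage that restricts
comparisons to pairs agreeing exactly on a small key set (date of birth
and hospital in the first pass, alternative key pairs in later passes so
that records with a transposed date of birth or a miskeyed hospital still
surface), and a scoring stage that computes the additive link score for
every candidate in a block.  A maternal link is accepted only when the
required triple links (mother's DOB — possibly via the transposition /
year relaxation — infant's DOB, and hospital), at least one other
variable links, and the score reaches the maternal cutoff (default 40).
An infant link is accepted only when infant sex is concordant and the
score reaches the infant cutoff (default 31).  Per record, the accepted
candidate with the highest score wins; exact score ties are broken
uniformly at random with a seeded, record-keyed generator, so results are
reproducible and independent of processing order.  Previously linked
records are removed before each pass; records unlinked after the final
pass stay unlinked.

Multiple-gestation deliveries may share one maternal episode across the
sibling set, but only when both sources classify the birth as a multiple
birth; same-sex multiples whose hospital records are field-identical are
assigned at random and flagged as ambiguous.

A longitudinal step attaches further hospital/ED/ambulatory-surgery
episodes to already-linked people inside a fixed window (one year either
side of delivery for the birthing person, the first year of life for the
infant).  An encrypted-SSN match alone is never sufficient: at least one
further variable must agree; without SSN evidence a person-level score
over the demographic comparators is required.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from datetime import timedelta
from typing import Mapping, Sequence

import numpy as np

from .config import BlockingPass, LinkageConfig
from .icd import ClinicalIndicators, derive_indicators, is_pregnancy_or_birth_record
from .records import HospitalEpisode, VitalRecord
from .scoring import (ComparatorSpec, ScoreBreakdown, compare_date,
                      default_comparator_spec, score_infant_pair,
                      score_mother_pair)

__all__ = [
    "Assignment",
    "LinkageResult",
    "generate_candidates",
    "accept_mother",
    "accept_infant",
    "link_mothers",
    "link_infants",
    "resolve_multiples",
    "link_longitudinal",
    "link_all",
    "record_rng",
]


@dataclass(frozen=True)
class Assignment:
    """One accepted link: episode, pass provenance, score, tie-break flag."""

    episode_id: str
    pass_label: str
    score: int
    tiebreak_used: bool = False


@dataclass
class LinkageResult:
    """Accepted assignments per side plus longitudinal attachments.

    ``mother`` and ``infant`` map vital ``record_id`` to an
    :class:`Assignment`; ``longitudinal`` maps person keys (``"M:<id>"`` /
    ``"I:<id>"``) to admission-ordered episode-id lists (anchor first).
    """

    mother: dict[str, Assignment] = field(default_factory=dict)
    infant: dict[str, Assignment] = field(default_factory=dict)
    unlinked_mother: list[str] = field(default_factory=list)
    unlinked_infant: list[str] = field(default_factory=list)
    longitudinal: dict[str, list[str]] = field(default_factory=dict)
    pass_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def record_rng(seed: int, record_id: str) -> np.random.Generator:
    """Seeded RNG keyed by record id.

    Keying by record makes every random choice a pure function of
    (seed, record) — reproducible, and independent of the order in which
    records happen to be processed.
    """
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(record_id.encode())])


def accept_mother(b: ScoreBreakdown, cfg: LinkageConfig) -> bool:
    """Required triple (with the DOB relaxation) + >=1 other variable + cutoff."""
    return (b.mother_dob_linked and b.infant_dob_linked and b.hospital_linked
            and b.other_variable_linked and b.total >= cfg.mother_cutoff)


def accept_infant(b: ScoreBreakdown, cfg: LinkageConfig) -> bool:
    """Concordant infant sex is mandatory regardless of score; then the cutoff."""
    return b.sex_concordant and b.total >= cfg.infant_cutoff


# ---------------------------------------------------------------------------
# Blocking
# ---------------------------------------------------------------------------

def _vital_keys(v: VitalRecord, key: str) -> tuple:
    if key == "mother_dob":
        return (v.mother_dob,) if v.mother_dob else ()
    if key == "infant_dob":
        return (v.infant_dob,)
    if key == "hospital":
        return (v.hospital_id,) if v.hospital_id else ()
    if key == "zip":
        return (v.zip,) if v.zip else ()
    if key == "sex":
        return (v.infant_sex,) if v.infant_sex in ("M", "F") else ()
    if key == "payer":
        return (v.payer,) if v.payer != "unknown" else ()
    if key == "preterm":
        return (v.gestational_age_wk < 37,) if v.gestational_age_wk is not None else ()
    raise ValueError(f"unknown blocking key {key!r}")


def _episode_keys(e: HospitalEpisode, ind: ClinicalIndicators, key: str,
                  side: str) -> tuple:
    if key == "mother_dob":
        return (e.patient_dob,) if e.patient_dob else ()
    if key == "infant_dob":
        if side == "infant":
            return (e.patient_dob,) if e.patient_dob else ()
        # Maternal abstracts carry no infant DOB; any date in the admission
        # window can block (capped to keep block keys bounded).
        span = min((e.discharge_date - e.admit_date).days, 14)
        return tuple(e.admit_date + timedelta(days=d) for d in range(span + 1))
    if key == "hospital":
        return (e.hospital_id,) if e.hospital_id else ()
    if key == "zip":
        return (e.zip,) if e.zip else ()
    if key == "sex":
        return (e.sex,) if e.sex in ("M", "F") else ()
    if key == "payer":
        return (e.payer,) if e.payer != "unknown" else ()
    if key == "preterm":
        return (ind.ga_band in ("lt29", "29to36"),) if ind.ga_band != "unknown" else ()
    raise ValueError(f"unknown blocking key {key!r}")


def generate_candidates(vitals: Sequence[VitalRecord],
                        episodes: Sequence[HospitalEpisode],
                        blocking_pass: BlockingPass,
                        indicators: Mapping[str, ClinicalIndicators],
                        side: str = "mother") -> list[tuple[VitalRecord, HospitalEpisode]]:
    """All and only pairs agreeing exactly on every blocking key of the pass.

    A record missing any key value generates no candidates in this pass.
    """
    from itertools import product

    index: dict[tuple, list[HospitalEpisode]] = {}
    for e in episodes:
        value_sets = [_episode_keys(e, indicators[e.episode_id], k, side)
                      for k in blocking_pass.keys]
        if any(not vs for vs in value_sets):
            continue
        for combo in product(*value_sets):
            index.setdefault(combo, []).append(e)
    out = []
    for v in vitals:
        value_sets = [_vital_keys(v, k) for k in blocking_pass.keys]
        if any(not vs for vs in value_sets):
            continue
        seen: set[str] = set()
        for combo in product(*value_sets):
            for e in index.get(combo, ()):
                if e.episode_id not in seen:
                    seen.add(e.episode_id)
                    out.append((v, e))
    return out


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _select_pass(accepted: list[tuple[VitalRecord, HospitalEpisode, ScoreBreakdown]],
                 pass_label: str, cfg: LinkageConfig, side: str,
                 consumed: dict[str, str],
                 assignments: dict[str, Assignment]) -> None:
    """Greedy per-record selection within one pass.

    Records are processed in descending order of their best candidate
    score (so a contested episode goes to the higher-scoring claimant);
    exact ties among a record's best candidates are broken uniformly at
    random with the record-keyed RNG.  A maternal episode consumed by one
    record stays available to that record's siblings only.
    """
    by_vital: dict[str, list[tuple[HospitalEpisode, ScoreBreakdown]]] = {}
    vital_by_id: dict[str, VitalRecord] = {}
    for v, e, b in accepted:
        by_vital.setdefault(v.record_id, []).append((e, b))
        vital_by_id[v.record_id] = v
    order = sorted(by_vital,
                   key=lambda rid: (-max(b.total for _, b in by_vital[rid]), rid))
    for rid in order:
        v = vital_by_id[rid]
        avail = [(e, b) for e, b in by_vital[rid]
                 if e.episode_id not in consumed
                 or (side == "mother" and consumed[e.episode_id] == v.sibling_set_id)]
        if not avail:
            continue
        best = max(b.total for _, b in avail)
        top = sorted((e.episode_id for e, b in avail if b.total == best))
        tie = len(top) > 1
        chosen = top[record_rng(cfg.rng_seed, rid).integers(len(top))] if tie else top[0]
        consumed[chosen] = v.sibling_set_id if side == "mother" else rid
        assignments[rid] = Assignment(episode_id=chosen, pass_label=pass_label,
                                      score=best, tiebreak_used=tie)


def _run_passes(vitals, episodes, passes, cfg, side, score_fn, accept_fn,
                indicators, spec) -> tuple[dict[str, Assignment], dict[str, dict[str, int]]]:
    if len({p.label for p in passes}) != len(passes):
        raise ValueError("duplicate pass labels in schedule")
    assignments: dict[str, Assignment] = {}
    consumed: dict[str, str] = {}
    pass_counts: dict[str, dict[str, int]] = {}
    remaining_v = list(vitals)
    for blocking_pass in passes:
        remaining_v = [v for v in remaining_v if v.record_id not in assignments]
        remaining_e = [e for e in episodes
                       if e.episode_id not in consumed or side == "mother"]
        if side == "mother":
            # Shared maternal episodes stay visible to siblings; others drop.
            sib_of = {v.record_id: v.sibling_set_id for v in remaining_v}
            open_sets = set(sib_of.values())
            remaining_e = [e for e in remaining_e
                           if e.episode_id not in consumed
                           or consumed[e.episode_id] in open_sets]
        if not remaining_v:
            break
        cands = generate_candidates(remaining_v, remaining_e, blocking_pass,
                                    indicators, side)
        accepted = []
        for v, e in cands:
            b = score_fn(v, e, indicators[e.episode_id], spec)
            if not accept_fn(b, cfg):
                continue
            if (cfg.require_plurality_concordance and side == "mother"
                    and v.plurality in ("twin", "multiple")
                    and indicators[e.episode_id].plurality not in ("twin", "multiple")):
                continue  # multiples must be classified as multiples in both
            accepted.append((v, e, b))
        before = len(assignments)
        _select_pass(accepted, blocking_pass.label, cfg, side, consumed, assignments)
        pass_counts[blocking_pass.label] = {
            "candidates": len(cands), "accepted_pairs": len(accepted),
            "linked": len(assignments) - before,
        }
    return assignments, pass_counts


def _indicator_map(episodes, code_sets=None) -> dict[str, ClinicalIndicators]:
    return {e.episode_id: derive_indicators(e, code_sets) for e in episodes}


def link_mothers(vitals: Sequence[VitalRecord], episodes: Sequence[HospitalEpisode],
                 cfg: LinkageConfig, spec: ComparatorSpec | None = None,
                 indicators: Mapping[str, ClinicalIndicators] | None = None) -> LinkageResult:
    """Run the maternal pass schedule over plausible delivery episodes."""
    spec = spec or default_comparator_spec()
    episodes = [e for e in episodes if is_pregnancy_or_birth_record(e)]
    indicators = indicators or _indicator_map(episodes)
    assignments, counts = _run_passes(vitals, episodes, cfg.maternal_passes, cfg,
                                      "mother", score_mother_pair, accept_mother,
                                      indicators, spec)
    result = LinkageResult(mother=assignments)
    result.unlinked_mother = [v.record_id for v in vitals
                             if v.record_id not in assignments]
    result.pass_counts = {f"mother:{k}": v for k, v in counts.items()}
    return result


def link_infants(vitals: Sequence[VitalRecord], episodes: Sequence[HospitalEpisode],
                 cfg: LinkageConfig, spec: ComparatorSpec | None = None,
                 indicators: Mapping[str, ClinicalIndicators] | None = None) -> LinkageResult:
    """Run the infant pass schedule; fetal deaths have no infant record to link."""
    spec = spec or default_comparator_spec()
    live = [v for v in vitals if not v.is_fetal_death]
    episodes = [e for e in episodes if is_pregnancy_or_birth_record(e)]
    indicators = indicators or _indicator_map(episodes)
    assignments, counts = _run_passes(live, episodes, cfg.infant_passes, cfg,
                                      "infant", score_infant_pair, accept_infant,
                                      indicators, spec)
    result = LinkageResult(infant=assignments)
    result.unlinked_infant = [v.record_id for v in live
                             if v.record_id not in assignments]
    result.pass_counts = {f"infant:{k}": v for k, v in counts.items()}
    return result


# ---------------------------------------------------------------------------
# Multiples
# ---------------------------------------------------------------------------

def _exchange_signature(e: HospitalEpisode, ind: ClinicalIndicators) -> tuple:
    # Multiples are indistinguishable when sex, birthweight band, delivery
    # mode, and survival all agree on the hospital side.
    return (e.sex, ind.birthweight_band, ind.cesarean, e.discharge_status == "died")


def resolve_multiples(vitals: Sequence[VitalRecord], result: LinkageResult,
                      episodes: Sequence[HospitalEpisode], cfg: LinkageConfig,
                      indicators: Mapping[str, ClinicalIndicators] | None = None) -> LinkageResult:
    """Enforce the multiple-birth rules and randomize undecipherable twins.

    Maternal links of multiple-gestation records are dropped unless the
    hospital side also classifies the birth as a multiple birth.  Within a
    sibling set, infant episodes that are field-identical (same sex,
    birthweight band, delivery mode, and survival) cannot be told apart,
    so they are reassigned uniformly at random (seeded by the sibling set)
    and flagged as tie-broken on every affected record.
    """
    episodes_by_id = {e.episode_id: e for e in episodes}
    indicators = dict(indicators) if indicators else {}

    def _ind(episode_id: str) -> ClinicalIndicators:
        if episode_id not in indicators:
            indicators[episode_id] = derive_indicators(episodes_by_id[episode_id])
        return indicators[episode_id]

    by_set: dict[str, list[VitalRecord]] = {}
    for v in vitals:
        by_set.setdefault(v.sibling_set_id, []).append(v)
    for set_id, sibs in by_set.items():
        if len(sibs) < 2:
            continue
        for v in sibs:  # plurality must be multiple in both sources
            a = result.mother.get(v.record_id)
            if a is None or not cfg.require_plurality_concordance:
                continue
            if a.episode_id not in episodes_by_id:
                continue
            if _ind(a.episode_id).plurality not in ("twin", "multiple"):
                del result.mother[v.record_id]
                result.unlinked_mother.append(v.record_id)
        # Shuffle infant assignments within exchangeable groups.
        linked = [(v, result.infant[v.record_id]) for v in sibs
                  if v.record_id in result.infant
                  and result.infant[v.record_id].episode_id in episodes_by_id]
        groups: dict[tuple, list[tuple[VitalRecord, Assignment]]] = {}
        for v, a in linked:
            ep = episodes_by_id[a.episode_id]
            groups.setdefault(_exchange_signature(ep, _ind(a.episode_id)), []).append((v, a))
        for members in groups.values():
            if len(members) < 2:
                continue
            rng = record_rng(cfg.rng_seed, "sibset:" + set_id)
            eids = [a.episode_id for _, a in sorted(members, key=lambda m: m[0].record_id)]
            perm = rng.permutation(len(eids))
            for (v, a), j in zip(sorted(members, key=lambda m: m[0].record_id), perm):
                result.infant[v.record_id] = replace(a, episode_id=eids[j],
                                                     tiebreak_used=True)
    return result


# ---------------------------------------------------------------------------
# Longitudinal linkage
# ---------------------------------------------------------------------------

_PERSON_VARS = ("zip", "county", "payer", "race_eth")


def _person_match_count(v: VitalRecord, e: HospitalEpisode, side: str) -> int:
    """Count agreeing person-level variables beyond the SSN."""
    n = 0
    ref_dob = v.mother_dob if side == "mother" else v.infant_dob
    if ref_dob is not None and e.patient_dob == ref_dob:
        n += 1
    for var in _PERSON_VARS:
        a, b = getattr(v, var), getattr(e, var)
        if a not in (None, "unknown") and a == b:
            n += 1
    if side == "infant" and v.infant_sex in ("M", "F") and v.infant_sex == e.sex:
        n += 1
    return n


def _person_score(v: VitalRecord, e: HospitalEpisode, side: str,
                  spec: ComparatorSpec) -> tuple[int, bool]:
    """Demographic score for the no-SSN longitudinal path.

    Returns (score, dob_linked): the patient's own date of birth must link
    (exact or transposed) and the person-level comparator subset must
    reach the longitudinal cutoff.
    """
    ref_dob = v.mother_dob if side == "mother" else v.infant_dob
    dob_level = compare_date(ref_dob, e.patient_dob)
    score = spec.value("mother_dob", dob_level) if dob_level != "none" else 0
    for var, vital_attr in (("zip", "zip"), ("payer", "payer"), ("county", "county")):
        a, b = getattr(v, vital_attr), getattr(e, var)
        if a not in (None, "unknown") and a == b:
            score += spec.value(var, "exact")
    if v.race_eth != "unknown" and v.race_eth == e.race_eth:
        from .scoring import _race_level
        score += spec.value("race", _race_level(v.race_eth, e.race_eth))
        score += spec.value("ethnicity", "exact")
    if side == "infant" and v.infant_sex in ("M", "F") and v.infant_sex == e.sex:
        score += spec.value("sex", "exact")
    return score, dob_level in ("exact", "transposed")


def link_longitudinal(vitals: Sequence[VitalRecord], result: LinkageResult,
                      all_episodes: Sequence[HospitalEpisode], cfg: LinkageConfig,
                      spec: ComparatorSpec | None = None) -> LinkageResult:
    """Attach additional episodes to linked people inside their windows.

    For the birthing person the window runs one year before to one year
    after delivery; for the infant, birth to one year.  With matching
    encrypted SSNs at least one further variable must also match (SSN
    alone is never a link); mismatching SSNs reject; without SSN evidence
    a person-level demographic score (with the patient's DOB linked) must
    reach ``cfg.longitudinal_cutoff``.
    """
    spec = spec or default_comparator_spec()
    episodes_by_id = {e.episode_id: e for e in all_episodes}
    window = timedelta(days=cfg.longitudinal_window_days)
    # Any attachable episode either shares the anchor's SSN or has a linked
    # (exact/transposed) patient DOB, so candidate lookup can be indexed.
    by_ssn: dict[str, list[HospitalEpisode]] = {}
    by_dob: dict = {}
    for e in all_episodes:
        if e.enc_ssn is not None:
            by_ssn.setdefault(e.enc_ssn, []).append(e)
        if e.patient_dob is not None:
            by_dob.setdefault(e.patient_dob, []).append(e)
    vital_by_id = {v.record_id: v for v in vitals}
    for side, assignments, prefix in (("mother", result.mother, "M"),
                                      ("infant", result.infant, "I")):
        for rid, anchor in assignments.items():
            v = vital_by_id.get(rid)
            anchor_ep = episodes_by_id.get(anchor.episode_id)
            if v is None or anchor_ep is None:
                continue
            if side == "mother":
                lo, hi = v.infant_dob - window, v.infant_dob + window
            else:
                lo, hi = v.infant_dob, v.infant_dob + window
            ref_dob = v.mother_dob if side == "mother" else v.infant_dob
            candidates: dict[str, HospitalEpisode] = {}
            if anchor_ep.enc_ssn is not None:
                for e in by_ssn.get(anchor_ep.enc_ssn, ()):
                    candidates[e.episode_id] = e
            if ref_dob is not None:
                for e in by_dob.get(ref_dob, ()):
                    candidates[e.episode_id] = e
                if ref_dob.day <= 12 and ref_dob.day != ref_dob.month:
                    swapped = ref_dob.replace(month=ref_dob.day, day=ref_dob.month)
                    for e in by_dob.get(swapped, ()):
                        candidates[e.episode_id] = e
            attached = []
            for e in candidates.values():
                if e.episode_id == anchor.episode_id:
                    continue
                if not (lo <= e.admit_date <= hi):
                    continue
                if e.enc_ssn is not None and anchor_ep.enc_ssn is not None:
                    if e.enc_ssn != anchor_ep.enc_ssn:
                        continue
                    extra = _person_match_count(v, e, side)
                    ok = extra >= 1 if cfg.ssn_requires_extra_variable else True
                else:
                    score, dob_ok = _person_score(v, e, side, spec)
                    ok = dob_ok and score >= cfg.longitudinal_cutoff
                if ok:
                    attached.append(e)
            attached.sort(key=lambda e: (e.admit_date, e.episode_id))
            result.longitudinal[f"{prefix}:{rid}"] = (
                [anchor.episode_id] + [e.episode_id for e in attached])
    return result


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def link_all(vitals: Sequence[VitalRecord],
             mother_episodes: Sequence[HospitalEpisode],
             infant_episodes: Sequence[HospitalEpisode],
             cfg: LinkageConfig,
             spec: ComparatorSpec | None = None,
             longitudinal: bool = True) -> LinkageResult:
    """Principal maternal + infant linkage, multiples resolution, longitudinal."""
    spec = spec or default_comparator_spec()
    m = link_mothers(vitals, mother_episodes, cfg, spec)
    i = link_infants(vitals, infant_episodes, cfg, spec)
    result = LinkageResult(mother=m.mother, infant=i.infant,
                           unlinked_mother=m.unlinked_mother,
                           unlinked_infant=i.unlinked_infant,
                           pass_counts={**m.pass_counts, **i.pass_counts})
    resolve_multiples(vitals, result, list(mother_episodes) + list(infant_episodes),
                      cfg)
    if longitudinal:
        link_longitudinal(vitals, result,
                          list(mother_episodes) + list(infant_episodes), cfg, spec)
    return result
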