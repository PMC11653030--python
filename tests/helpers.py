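"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

from datetime import date

from vitalink.engine import (Assignment, LinkageResult, accept_infant,
                             accept_mother, record_rng, resolve_multiples)
from vitalink.icd import derive_indicators, is_pregnancy_or_birth_record
from vitalink.records import HospitalEpisode, VitalRecord
from vitalink.scoring import score_infant_pair, score_mother_pair


def make_vital(**kw) -> VitalRecord:
    base = dict(record_id="V1", year=2012, infant_dob=date(2012, 3, 9),
                sibling_set_id="S1", mother_dob=date(1985, 6, 21),
                hospital_id="H1", zip="90210", county="C1", payer="private",
                race_eth="asian", infant_sex="F", gestational_age_wk=39,
                birthweight_g=3300, plurality="singleton", birth_order=1,
                education="gt12", mother_age_yrs=26)
    base.update(kw)
    return VitalRecord(**base)


def make_episode(**kw) -> HospitalEpisode:
    base = dict(episode_id="E1", person_role="mother", record_type="PDD",
                hospital_id="H1", admit_date=date(2012, 3, 9),
                discharge_date=date(2012, 3, 11), patient_dob=date(1985, 6, 21),
                zip="90210", county="C1", payer="private", race_eth="asian",
                sex="F", diagnosis_codes=(("icd10", "O80"),),
                procedure_codes=(), mdc=14, discharge_status="routine",
                age_at_admission_yrs=26)
    base.update(kw)
    return HospitalEpisode(**base)


def maximal_pair() -> tuple[VitalRecord, HospitalEpisode]:
    """A pair concordant at the highest-scoring level of every variable.

    Gestation <29 wk (20), birthweight >=4500 g (10, and the only band
    compatible with a certificate-side large-for-gestational-age flag),
    minority race match (10), twin plurality (10), infant death (10),
    plus every 10/7/5/2-point comparator at its maximum.
    """
    v = make_vital(gestational_age_wk=27, birthweight_g=4600, plurality="twin",
                   birth_order=1, cesarean=True, previous_cesarean=True,
                   infant_death=True,
                   conditions=frozenset({"hypertension_preg", "diabetes_any"}))
    e = make_episode(
        discharge_status="died",
        diagnosis_codes=(("icd10", "P07.2"),   # gestation <29 wk
                         ("icd10", "P08.0"),   # birthweight >=4500 g
                         ("icd9", "764.0"),    # SGA/LGA
                         ("icd9", "642.3"),    # hypertension in pregnancy
                         ("icd10", "O24.4"),   # diabetes
                         ("icd10", "O34.2"),   # previous cesarean
                         ("icd10", "O82"),     # cesarean delivery
                         ("icd9", "651.0")),   # twin gestation
    )
    return v, e


def all_pairs_link(vitals, mother_eps, infant_eps, cfg) -> LinkageResult:
    """Exhaustive all-pairs score-filter-select oracle (no blocking, one shot).

    Every (vital, episode) pair on each side is scored and filtered with
    the published acceptance rules; selection is greedy in descending
    best-candidate score with the same record-keyed tie-break contract as
    the engine, so on identical candidate sets the two make identical
    choices.  Multiples resolution is shared: the oracle targets the
    blocking and selection machinery.
    """
    result = LinkageResult()
    for side, eps, score_fn, accept_fn in (
            ("mother", mother_eps, score_mother_pair, accept_mother),
            ("infant", infant_eps, score_infant_pair, accept_infant)):
        eps = [e for e in eps if is_pregnancy_or_birth_record(e)]
        ind = {e.episode_id: derive_indicators(e) for e in eps}
        vs = (list(vitals) if side == "mother"
              else [v for v in vitals if not v.is_fetal_death])
        accepted: dict[str, list[tuple[str, int]]] = {}
        vit = {}
        for v in vs:
            for e in eps:
                b = score_fn(v, e, ind[e.episode_id])
                if not accept_fn(b, cfg):
                    continue
                if (side == "mother" and cfg.require_plurality_concordance
                        and v.plurality in ("twin", "multiple")
                        and ind[e.episode_id].plurality not in ("twin", "multiple")):
                    continue
                accepted.setdefault(v.record_id, []).append((e.episode_id, b.total))
                vit[v.record_id] = v
        consumed: dict[str, str] = {}
        assignments = getattr(result, side)
        order = sorted(accepted, key=lambda r: (-max(t for _, t in accepted[r]), r))
        for rid in order:
            v = vit[rid]
            avail = [(eid, t) for eid, t in accepted[rid]
                     if eid not in consumed
                     or (side == "mother" and consumed[eid] == v.sibling_set_id)]
            if not avail:
                continue
            best = max(t for _, t in avail)
            top = sorted(eid for eid, t in avail if t == best)
            tie = len(top) > 1
            chosen = (top[record_rng(cfg.rng_seed, rid).integers(len(top))]
                      if tie else top[0])
            consumed[chosen] = v.sibling_set_id if side == "mother" else rid
            assignments[rid] = Assignment(chosen, "oracle", best, tie)
    resolve_multiples(vitals, result, list(mother_eps) + list(infant_eps), cfg)
    return result


def assignments_equal(eng: LinkageResult, ora: LinkageResult, truth) -> list[str]:
    """Differences between two results, up to exchangeable-multiple swaps."""
    diffs = []
    for side in ("mother", "infant"):
        a, b = getattr(eng, side), getattr(ora, side)
        if set(a) != set(b):
            diffs.append(f"{side}: linked sets differ by {sorted(set(a) ^ set(b))}")
            continue
        for rid in a:
            if a[rid].episode_id == b[rid].episode_id:
                if a[rid].score != b[rid].score:
                    diffs.append(f"{side}:{rid}: scores {a[rid].score} != {b[rid].score}")
                continue
            exch = truth.infant_exchangeable.get(rid, frozenset())
            if not (side == "infant" and a[rid].episode_id in exch
                    and b[rid].episode_id in exch):
                diffs.append(f"{side}:{rid}: {a[rid].episode_id} != {b[rid].episode_id}")
    return diffs
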