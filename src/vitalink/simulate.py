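"""Ground-truthed synthetic maternal-infant cohort generator.

Each simulated delivery yields one vital record per fetus (sharing a
sibling-set id), one maternal delivery episode unless withheld, and one
infant birth episode per live-born infant unless withheld; fetal deaths
produce no infant episode.  Episode fields are copied from the truth and
then perturbed by an independent per-field error model (date
transposition, field deletion, zip typos) chosen to exercise every
comparator branch of the link score.  ICD codes are written consistently
with the generated indicators, so indicator derivation inverts the
generation exactly on unperturbed episodes.  A truth table records the
correct counterpart of every vital record (``None`` when withheld), every
perturbation applied, and — for multiples whose hospital records are
field-identical — the exchangeable episode set that no linkage algorithm
could tell apart.

The generator emulates the statistical structure of statewide birth-cohort
and hospital files (marginal rates, per-source condition recording,
encrypted-SSN coverage), not their geography or native layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
import numpy as np

from .config import SimulationConfig
from .records import HospitalEpisode, VitalRecord

__all__ = ["TruthTable", "simulate_cohort", "perturb_record"]

_GA_BAND_WEEKS = {"20-27": (20, 27), "28-31": (28, 31), "32-36": (32, 36),
                  "37-42": (37, 42), "43-44": (43, 44)}
_BW_MEAN_SD = {"20-27": (900, 300), "28-31": (1600, 400), "32-36": (2450, 500),
               "37-42": (3400, 450), "43-44": (3600, 450), "missing": (3300, 500)}
_DEATH_MULT = {"20-27": 80.0, "28-31": 20.0, "32-36": 4.0, "37-42": 1.0,
               "43-44": 1.2, "missing": 1.5}

# (icd9 code, icd10 code) written for each indicator level; one of the two
# is chosen by the episode's coding era, falling back to the other system
# where a level has no code in the era's system (both columns are matched
# at derivation time, so mixed-system records are handled).
_GA_CODES = {"lt29": ("765.21", "P07.2"), "29to36": ("765.25", "O60.1"),
             "37to42": ("765.29", None), "gt42": (None, "P08.22")}
_BW_CODES = {"lt2500": ("765.11", "P05.11"), "2500to4499": ("765.19", "P05.19"),
             "ge4500": (None, "P08.0")}
_PLURALITY_CODES = {"singleton": ("V27.0", "Z38.00"), "twin": ("651.0", "O30.0"),
                    "multiple": ("651.1", "O30.1")}
_CONDITION_CODES = {
    "gestational_diabetes": ("648.81", "O24.42"),
    "preexisting_diabetes": ("250.00", "O24.01"),
    "prepregnancy_hypertension": ("642.03", "O10.91"),
    "gestational_hypertension": ("642.33", "O13.9"),
    "eclampsia": ("642.63", "O15.9"),
    "placental_abruption": ("641.21", "O45.90"),
    "chorioamnionitis": ("658.41", "O41.12"),
    "neural_tube_defect": ("741.90", "Q05.9"),
    "gastroschisis_omphalocele": ("756.73", "Q79.3"),
    "cleft_lip_palate": ("749.00", "Q35.9"),
    "major_heart_defect": ("745.4", "Q21.0"),
}
# O36.5x rather than a P05.x code: P05 prefixes double as birthweight bands.
_SGA_CODES = ("764.01", "O36.59")
_CESAREAN_DX = ("669.71", "O82")
_CESAREAN_PX = ("74.1", "10D00Z1")
_PREV_CESAREAN = ("654.21", "O34.21")
_MATERNAL_BASE = ("650", "O80")
_NEWBORN_BASE = {"singleton": ("V30.00", "Z38.00"), "twin": ("V31.00", "Z38.30"),
                 "multiple": ("V37.00", "Z38.61")}


@dataclass
class TruthTable:
    """Ground truth for a simulated cohort.

    ``mother_episode`` / ``infant_episode`` map every vital record id to
    its true counterpart episode id (``None`` when the episode was
    withheld or, for infants, when the record is a fetal death).
    ``infant_exchangeable`` lists, per record, every infant episode a
    perfect algorithm could defensibly assign (its own plus any
    field-identical sibling episode).  ``extra_episodes`` holds the
    longitudinal truth: (episode id, within-window flag) per person side.
    """

    mother_episode: dict[str, str | None] = field(default_factory=dict)
    infant_episode: dict[str, str | None] = field(default_factory=dict)
    perturbations: dict[str, list[str]] = field(default_factory=dict)
    infant_exchangeable: dict[str, frozenset[str]] = field(default_factory=dict)
    extra_episodes: dict[str, list[tuple[str, bool]]] = field(default_factory=dict)


def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _code(pair: tuple[str | None, str | None], era: str) -> tuple[str, str]:
    icd9, icd10 = pair
    if era == "icd9" and icd9 is not None:
        return ("icd9", icd9)
    if icd10 is not None:
        return ("icd10", icd10)
    return ("icd9", icd9)


def _scoring_ga_band(wk: int | None) -> str:
    if wk is None:
        return "missing"
    if wk < 29:
        return "lt29"
    if wk < 37:
        return "29to36"
    if wk <= 42:
        return "37to42"
    return "gt42"


def _bw_band(g: int) -> str:
    return "lt2500" if g < 2500 else ("2500to4499" if g < 4500 else "ge4500")


def perturb_record(episode: HospitalEpisode, cfg: SimulationConfig,
                   rng: np.random.Generator) -> tuple[HospitalEpisode, list[str]]:
    """Apply the independent per-field error model to one episode.

    Returns the perturbed episode and the perturbation log.  A date
    transposition requires day <= 12 and month != day to produce a valid,
    distinct date; otherwise it is logged as inapplicable.
    """
    log: list[str] = []
    changes: dict = {}
    # Every probability is always consumed from the stream, so cohorts
    # generated at different error levels from one seed are coupled: the
    # perturbations at a lower level are a subset of those at a higher one.
    if rng.random() < cfg.p_dob_transposed:
        dob = episode.patient_dob
        if dob is not None and dob.day <= 12 and dob.month != dob.day:
            changes["patient_dob"] = date(dob.year, dob.day, dob.month)
            log.append("dob_transposed")
        else:
            log.append("dob_transposed_inapplicable")
    for fieldname in ("zip", "county", "payer", "race_eth"):
        if rng.random() < cfg.p_field_missing:
            if fieldname in ("payer", "race_eth"):
                changes[fieldname] = "unknown"
            else:
                changes[fieldname] = None
            log.append(f"{fieldname}_missing")
    if rng.random() < cfg.p_zip_error:
        zip_now = changes.get("zip", episode.zip)
        if zip_now:
            pos = int(rng.integers(len(zip_now)))
            digit = str(int(rng.integers(10)))
            if digit == zip_now[pos]:
                digit = str((int(digit) + 1) % 10)
            changes["zip"] = zip_now[:pos] + digit + zip_now[pos + 1:]
            log.append("zip_error")
    return (replace(episode, **changes) if changes else episode), log


def _withhold_prob(base: float, payer: str, cfg: SimulationConfig) -> float:
    if cfg.withholding_payer_multiplier:
        return min(1.0, base * cfg.withholding_payer_multiplier.get(payer, 1.0))
    return base


def simulate_cohort(cfg: SimulationConfig
                    ) -> tuple[list[VitalRecord], list[HospitalEpisode],
                               list[HospitalEpisode], TruthTable]:
    """Generate (vitals, mother_episodes, infant_episodes, truth).

    Deterministic under ``cfg.rng_seed``: a single seeded generator is
    consumed in a fixed per-delivery order.
    """
    rng = np.random.default_rng(cfg.rng_seed & 0x7FFFFFFF)
    vitals: list[VitalRecord] = []
    mother_eps: list[HospitalEpisode] = []
    infant_eps: list[HospitalEpisode] = []
    truth = TruthTable()

    for i in range(cfg.n_deliveries):
        set_id = f"S{i:07d}"
        year = int(rng.integers(cfg.year_start, cfg.year_end + 1))
        era = "icd9" if year < 2016 else "icd10"
        delivery = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))

        age_band = _choice(rng, cfg.age_band_probs)
        age = {"lt18": (15, 17), "18to34": (18, 34), "gt34": (35, 45),
               "missing": (18, 40)}[age_band]
        age_yrs = int(rng.integers(age[0], age[1] + 1))
        mother_dob = delivery - timedelta(days=age_yrs * 365 + int(rng.integers(0, 365)))
        mother_age = None if age_band == "missing" else age_yrs

        u = rng.random()
        n_fetuses = 3 if u < cfg.higher_multiple_rate else (
            2 if u < cfg.higher_multiple_rate + cfg.twin_rate else 1)
        plurality = ("singleton", "twin", "multiple")[min(n_fetuses, 3) - 1]

        hospital = f"H{int(rng.integers(cfg.n_hospitals)):03d}"
        zip_idx = int(rng.integers(cfg.n_zips))
        zip_code = f"9{zip_idx:04d}"
        county = f"C{zip_idx % cfg.n_counties:02d}"
        payer = _choice(rng, cfg.payer_probs)
        race = _choice(rng, cfg.race_probs)
        education = _choice(rng, cfg.education_probs)

        ga_stratum = _choice(rng, cfg.ga_band_probs)
        if ga_stratum == "missing":
            ga_wk = None
        else:
            lo, hi = _GA_BAND_WEEKS[ga_stratum]
            ga_wk = int(rng.integers(lo, hi + 1))
        ga_band = _scoring_ga_band(ga_wk)

        cesarean = bool(rng.random() < cfg.cesarean_rate)
        prev_cesarean = bool(rng.random() < cfg.previous_cesarean_rate)

        true_conditions = {name for name, c in cfg.conditions.items()
                           if rng.random() < c.prevalence}
        vs_conditions = {name for name in sorted(true_conditions)
                         if rng.random() < cfg.conditions[name].sens_vs}
        hospital_conditions = {name for name in sorted(true_conditions)
                          if rng.random() < cfg.conditions[name].sens_hospital}

        def scoring_labels(conds: set[str]) -> set[str]:
            out = set(conds)
            if conds & {"gestational_diabetes", "preexisting_diabetes"}:
                out.add("diabetes_any")
            if conds & {"prepregnancy_hypertension", "gestational_hypertension",
                        "eclampsia"}:
                out.add("hypertension_preg")
            return out

        mother_ssn = (f"SSN{i:09d}"
                      if rng.random() < cfg.enc_ssn_mother else None)

        # Shared maternal delivery episode codes (era-chosen, indicator-true).
        dx: list[tuple[str, str]] = [_code(_MATERNAL_BASE, era)]
        px: list[tuple[str, str]] = []
        if ga_band != "missing":
            dx.append(_code(_GA_CODES[ga_band], era))
        dx.append(_code(_PLURALITY_CODES[plurality], era))
        if cesarean:
            dx.append(_code(_CESAREAN_DX, era))
            px.append(_code(_CESAREAN_PX, era))
        if prev_cesarean:
            dx.append(_code(_PREV_CESAREAN, era))
        for cond in sorted(hospital_conditions):
            if cond not in ("neural_tube_defect", "gastroschisis_omphalocele",
                            "cleft_lip_palate", "major_heart_defect"):
                dx.append(_code(_CONDITION_CODES[cond], era))

        fetus_rows = []
        for j in range(n_fetuses):
            rid = f"V{i:07d}-{j + 1}"
            fetal_death = bool(rng.random() < cfg.fetal_death_rate)
            sex = "M" if rng.random() < 0.5 else "F"
            mean, sd = _BW_MEAN_SD[ga_stratum]
            bw = int(np.clip(rng.normal(mean, sd), 350, 5600))
            p_death = min(0.5, cfg.infant_death_rate * _DEATH_MULT[ga_stratum])
            infant_death = (None if fetal_death
                            else bool(rng.random() < p_death))
            fetus_rows.append((rid, j + 1, fetal_death, sex, bw, infant_death))

        mother_withheld = rng.random() < _withhold_prob(
            cfg.p_mother_unlinked, payer, cfg)
        admit_offset = int(rng.random() < 0.3)  # some admissions start a day early
        mother_eid = None
        if not mother_withheld:
            mother_eid = f"EM{i:07d}"
            ep = HospitalEpisode(
                episode_id=mother_eid, person_role="mother", record_type="PDD",
                hospital_id=hospital,
                admit_date=delivery - timedelta(days=admit_offset),
                discharge_date=delivery + timedelta(days=2),
                patient_dob=mother_dob, zip=zip_code, county=county,
                payer=payer, race_eth=race, sex="F",
                diagnosis_codes=tuple(dx), procedure_codes=tuple(px),
                mdc=14, discharge_status="routine", enc_ssn=mother_ssn,
                age_at_admission_yrs=age_yrs)
            ep, log = perturb_record(ep, cfg, rng)
            mother_eps.append(ep)
            for rid, *_ in fetus_rows:
                truth.perturbations.setdefault(rid, []).extend(
                    f"mother:{entry}" for entry in log)

        infant_truth_rows = []
        for rid, order, fetal_death, sex, bw, infant_death in fetus_rows:
            vitals.append(VitalRecord(
                record_id=rid, year=year, infant_dob=delivery,
                sibling_set_id=set_id, is_fetal_death=fetal_death,
                mother_dob=mother_dob, hospital_id=hospital, zip=zip_code,
                county=county, payer=payer, race_eth=race, infant_sex=sex,
                gestational_age_wk=ga_wk, birthweight_g=bw,
                plurality=plurality, birth_order=order,
                cesarean=cesarean, previous_cesarean=prev_cesarean,
                infant_death=infant_death, education=education,
                mother_age_yrs=mother_age,
                conditions=frozenset(scoring_labels(vs_conditions))))
            truth.mother_episode[rid] = mother_eid
            if fetal_death:
                truth.infant_episode[rid] = None
                continue
            if rng.random() < _withhold_prob(cfg.p_infant_unlinked, payer, cfg):
                truth.infant_episode[rid] = None
                continue
            eid = f"EI{i:07d}-{order}"
            bw_band = _bw_band(bw)
            idx: list[tuple[str, str]] = [_code(_NEWBORN_BASE[plurality], era)]
            ipx: list[tuple[str, str]] = []
            if ga_band != "missing":
                idx.append(_code(_GA_CODES[ga_band], era))
            idx.append(_code(_BW_CODES[bw_band], era))
            idx.append(_code(_PLURALITY_CODES[plurality], era))
            sga = bw >= 4500 or (ga_wk is not None and ga_wk >= 37 and bw < 2500)
            if sga:
                idx.append(_code(_SGA_CODES, era))
            if cesarean:
                idx.append(_code(_CESAREAN_DX, era))
                ipx.append(_code(_CESAREAN_PX, era))
            for cond in sorted(hospital_conditions):
                if cond in ("neural_tube_defect", "gastroschisis_omphalocele",
                            "cleft_lip_palate", "major_heart_defect"):
                    idx.append(_code(_CONDITION_CODES[cond], era))
            stay = 2 if ga_band in ("37to42", "gt42", "missing") else 21
            infant_ssn = (f"SSNI{i:07d}{order}"
                          if rng.random() < cfg.enc_ssn_infant else None)
            ep = HospitalEpisode(
                episode_id=eid, person_role="infant", record_type="PDD",
                hospital_id=hospital, admit_date=delivery,
                discharge_date=delivery + timedelta(days=stay),
                patient_dob=delivery, zip=zip_code, county=county,
                payer=payer, race_eth=race, sex=sex,
                diagnosis_codes=tuple(idx), procedure_codes=tuple(ipx),
                mdc=15, discharge_status="died" if infant_death else "routine",
                enc_ssn=infant_ssn, age_at_admission_yrs=0)
            ep, log = perturb_record(ep, cfg, rng)
            infant_eps.append(ep)
            truth.infant_episode[rid] = eid
            truth.perturbations.setdefault(rid, []).extend(
                f"infant:{entry}" for entry in log)
            infant_truth_rows.append((rid, eid, sex, bw_band, infant_death))

        # Exchangeable infant episodes: same sex, birthweight band, delivery
        # mode (shared within a delivery) and survival are undecipherable.
        for rid, eid, sex, bw_band, died in infant_truth_rows:
            group = frozenset(e for r2, e, s2, b2, d2 in infant_truth_rows
                              if (s2, b2, d2) == (sex, bw_band, died))
            truth.infant_exchangeable[rid] = group

        # Longitudinal extras (post/pre-delivery visits with truth labels).
        first_rid = fetus_rows[0][0]
        if mother_eid is not None and rng.random() < cfg.p_extra_episode_mother:
            outside = rng.random() < cfg.p_extra_outside_window
            offset = (int(rng.integers(400, 700)) if outside
                      else int(rng.integers(-360, 361)))
            if not outside and -3 <= offset <= 3:
                offset = 10  # keep clear of the delivery stay itself
            eid = f"XM{i:07d}"
            mother_eps.append(HospitalEpisode(
                episode_id=eid, person_role="mother", record_type="ED",
                hospital_id=hospital, admit_date=delivery + timedelta(days=offset),
                discharge_date=delivery + timedelta(days=offset),
                patient_dob=mother_dob, zip=zip_code, county=county,
                payer=payer, race_eth=race, sex="F",
                diagnosis_codes=(("icd10", "J45.909"),), procedure_codes=(),
                mdc=4, discharge_status="routine", enc_ssn=mother_ssn,
                age_at_admission_yrs=age_yrs))
            truth.extra_episodes.setdefault(f"M:{first_rid}", []).append(
                (eid, not outside))
        live_linked = [(rid, eid) for rid, eid, *_ in infant_truth_rows]
        if live_linked and rng.random() < cfg.p_extra_episode_infant:
            rid, _ = live_linked[0]
            outside = rng.random() < cfg.p_extra_outside_window
            offset = (int(rng.integers(400, 700)) if outside
                      else int(rng.integers(30, 360)))
            sex = next(s for r2, _, s, *_ in infant_truth_rows if r2 == rid)
            eid = f"XI{i:07d}"
            infant_eps.append(HospitalEpisode(
                episode_id=eid, person_role="infant", record_type="ED",
                hospital_id=hospital, admit_date=delivery + timedelta(days=offset),
                discharge_date=delivery + timedelta(days=offset),
                patient_dob=delivery, zip=zip_code, county=county,
                payer=payer, race_eth=race, sex=sex,
                diagnosis_codes=(("icd10", "J06.9"),), procedure_codes=(),
                mdc=4, discharge_status="routine", enc_ssn=None,
                age_at_admission_yrs=0))
            truth.extra_episodes.setdefault(f"I:{rid}", []).append(
                (eid, not outside))

    return vitals, mother_eps, infant_eps, truth
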