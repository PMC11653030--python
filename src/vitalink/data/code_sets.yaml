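# ICD-9/ICD-10 prefix sets behind the clinical indicators used by the
# linkage comparators and by the dual-source ascertainment evaluation.
#
# Matching is prefix-based on normalized codes (uppercased, dots stripped).
# Band indicators are mutually exclusive per field; when codes on one episode
# imply several levels of the same band, the first level listed in
# `priority` wins (extreme / high-scoring levels first).
#
# The `ascertainment` block is an editable default: these condition groupers
# are a reasonable reading of standard obstetric coding practice, NOT a
# published reference set, and users validating against chart review should
# replace them with their own groupers.

bands:
  ga_band:
    priority: [lt29, gt42, 29to36, 37to42]
    levels:
      lt29:
        icd9: ["765.21", "765.22", "765.23", "765.24"]
        icd10: ["P07.2"]
      29to36:
        icd9: ["765.25", "765.26", "765.27", "765.28"]
        icd10: ["O60.1", "O60.3", "P07.3"]
      37to42:
        icd9: ["765.29"]
        icd10: []
      gt42:
        icd9: []
        icd10: ["P08.22", "O48"]
  birthweight_band:
    priority: [lt2500, ge4500, 2500to4499]
    levels:
      lt2500:
        icd9: ["765.01", "765.02", "765.03", "765.04", "765.05", "765.06",
               "765.07", "765.08", "765.11", "765.12", "765.13", "765.14",
               "765.15", "765.16", "765.17", "765.18"]
        icd10: ["P05.01", "P05.02", "P05.03", "P05.04", "P05.05", "P05.07",
                "P05.08", "P05.11", "P05.12", "P05.13", "P05.14", "P05.15",
                "P05.17", "P05.18", "P07.0", "P07.1"]
      2500to4499:
        icd9: ["765.09", "765.19"]
        icd10: ["P05.09", "P05.19"]
      ge4500:
        icd9: []
        icd10: ["P08.0"]
  plurality:
    priority: [multiple, twin, singleton]
    levels:
      singleton:
        icd9: ["V27.0"]
        icd10: ["Z38.0", "Z38.1", "Z38.2"]
      twin:
        icd9: ["651.0"]
        icd10: ["O30.0", "Z38.3", "Z38.4", "Z38.5"]
      multiple:
        icd9: ["651.1", "651.2"]
        icd10: ["O30.1", "O30.2", "O38.8", "O38.9", "Z38.6", "Z38.7", "Z38.8"]

flags:
  cesarean:
    icd9: ["669.7", "763.4"]
    icd10: ["O82", "P03.4", "Z38.01", "Z38.31", "Z38.62"]
    icd9_proc: ["74"]
    icd10_proc: ["10D"]
  previous_cesarean:
    icd9: ["654.2"]
    icd10: ["O34.2"]
  sga_lga:
    icd9: ["656.5", "764.0", "764.1", "764.9"]
    icd10: ["P05", "O36.5"]
  hypertension_preg:
    icd9: ["642"]
    icd10: ["O1"]
  diabetes_any:
    icd9: ["648.0", "648.8", "250"]
    icd10: ["O24"]

# Editable defaults; not validated against any published grouper.
ascertainment:
  gestational_diabetes:
    icd9: ["648.8"]
    icd10: ["O24.4"]
  preexisting_diabetes:
    icd9: ["250", "648.0"]
    icd10: ["O24.0", "O24.1", "O24.3"]
  prepregnancy_hypertension:
    icd9: ["642.0", "642.1", "642.2"]
    icd10: ["O10", "O11"]
  gestational_hypertension:
    icd9: ["642.3", "642.4", "642.5", "642.7"]
    icd10: ["O13", "O14"]
  eclampsia:
    icd9: ["642.6"]
    icd10: ["O15"]
  placental_abruption:
    icd9: ["641.2"]
    icd10: ["O45"]
  chorioamnionitis:
    icd9: ["658.4"]
    icd10: ["O41.1"]
  neural_tube_defect:
    icd9: ["740", "741", "742.0"]
    icd10: ["Q00", "Q01", "Q05"]
  gastroschisis_omphalocele:
    icd9: ["756.7"]
    icd10: ["Q79.2", "Q79.3"]
  cleft_lip_palate:
    icd9: ["749"]
    icd10: ["Q35", "Q36", "Q37"]
  major_heart_defect:
    icd9: ["745", "746"]
    icd10: ["Q20", "Q21", "Q22", "Q23", "Q25"]
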