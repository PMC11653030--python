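# Methods

## The linkage model

The package links a base file of birth and fetal-death certificate records
to hospital discharge/ED/ambulatory-surgery episodes in two principal
steps (birthing person, then infant), followed by a longitudinal step that
collects each linked person's other hospital contacts around delivery.
The linkage is a deterministic/probabilistic hybrid in the tradition of
blocked additive-score matching rather than an EM-weighted Fellegi–Sunter
model: comparator weights are fixed constants chosen for variable
strength, not estimated match/unmatch likelihood ratios. The governing
assumptions are:

- **Candidate generation by exact-key blocking.** A pair is only ever
  compared when it agrees exactly on every key of some pass. The maternal
  schedule runs six passes (A: mother DOB + hospital; B: infant DOB + zip;
  C: infant DOB + hospital; D: mother DOB + zip; E: zip + hospital;
  F: preterm indicator + infant DOB); the infant schedule runs nine
  (A: hospital + infant DOB, with B–D repeating A so the remaining records
  of a twin or triplet delivery can claim the duplicate episodes;
  E: infant DOB + zip, F repeating E; G: zip + sex; H: zip + payer;
  I: zip + hospital). Previously linked records are removed between
  passes; records unlinked after the last pass stay unlinked. The printed
  maternal schedule labels two passes "C"; they are relabeled C and D
  here with the order preserved.
- **Additive scoring with hard eligibility.** The score is the sum of
  per-variable concordance points (0–148 over the full maternal table).
  Acceptance is pessimistic: a maternal link needs the required triple
  (mother DOB — transposition or a differing year tolerated — infant DOB,
  hospital) *and* at least one other linking variable *and* a score of at
  least 40; an infant link needs concordant sex and at least 31. A
  variable missing on either side contributes 0 points and cannot serve
  as the required "other" variable.
- **Per-record maximization with seeded tie-breaks.** Records are
  processed in descending order of their best candidate score, so a
  contested episode goes to the higher-scoring claimant; exact ties are
  broken uniformly at random.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| `mother_cutoff` | 40 points | minimum accepted maternal score |
| `infant_cutoff` | 31 points | minimum accepted infant score (fewer comparable variables exist on newborn records, hence the lower bar) |
| `longitudinal_cutoff` | 20 points | demographic score required on the no-SSN longitudinal path (patient DOB must link); chosen so that DOB alone never suffices but DOB + two mid-weight variables does |
| `longitudinal_window_days` | 365 | one year either side of delivery for the birthing person; birth to one year for the infant |
| `require_plurality_concordance` | true | multiple-gestation maternal links are dropped unless the hospital side is also coded twin/multiple |
| `ssn_requires_extra_variable` | true | an encrypted-SSN match alone is never a link |

The comparator point table and the ICD prefix sets ship as packaged YAML
(`vitalink/data/score_table.yaml`, `code_sets.yaml`) and can be overridden
for sensitivity analyses. Point-table invariants (non-negative integers,
148 per-variable-maximum sum for the shipped table) are validated on load.

Design choices made where the printed method is silent or ambiguous:

- **Date relaxation scope.** The eligibility relaxation covers the
  mother's DOB (transposed month/day, worth the printed 5 points, or a
  differing year, worth 0 but still eligible — the relaxation confers
  eligibility, not points) and a transposed infant DOB; the hospital must
  always link exactly. `dob_relaxation_used` is logged per pair.
- **Infant DOB on maternal abstracts.** Maternal discharge abstracts carry
  no infant-DOB field, so the infant's DOB counts as exactly linked when
  it falls inside the episode's admission window; transposition checking
  applies only to the mother's own DOB field.
- **Race/ethnicity.** Records carry one combined race/ethnicity category.
  A race match earns 5 points, +5 when the matching category is American
  Indian/Alaska Native, Asian, Hawaiian/Pacific Islander, Black, or other
  race, +2 when it is non-Hispanic White; Hispanic and multiple-race
  matches earn the base 5 only, since they appear in neither printed bonus
  list. Ethnicity (Hispanic vs not) is a separate 2-point comparator
  derived from the same field.
- **Plurality.** Twin and higher-order multiples form one 10-point
  concordance class; singleton–singleton earns 2.
- **Flag comparators score positive concordance only.** An absent ICD code
  is no evidence of absence, so cesarean/previous-cesarean/hypertension/
  diabetes/SGA-LGA/infant-death points require a positive on both sides.
- **Certificate-side SGA/LGA proxy.** Certificates carry no SGA/LGA field;
  the proxy flags term births under 2500 g and any birth at or above
  4500 g.
- **Band conflicts.** When codes on one episode imply several levels of a
  banded indicator, the extreme (high-scoring) level wins — the priority
  order is part of the packaged code-set config.
- **Newborn prefilter.** The pregnancy/birth restriction applied before
  infant linkage additionally accepts newborn-admission evidence (ICD-10
  Z38*, ICD-9 V30–V39, age 0 at admission); without it, infant birth
  stays would be filtered out by the maternity-only code ranges.
- **Tie-break RNG.** Random choices use a generator keyed by
  (seed, CRC-32 of the record id) — a pure function of seed and record,
  hence reproducible *and* independent of processing order. This
  replaces a single shared stream, whose output would depend on the order
  records happen to be visited, and it lets an independent selection
  procedure reproduce the engine's choices exactly.
- **Episode contention.** The original per-record description does not
  say how two records claiming the same episode are resolved; the engine
  processes records greedily in descending best-score order, which is
  deterministic and gives the episode to the stronger claimant. Only
  records of one sibling set may share a maternal episode.
- **Cutoffs are pass-invariant.** The 40/31 cutoffs and required-variable
  rules apply identically in every pass.

## The synthetic cohort generator

`simulate_cohort` emulates the *statistical* structure of a statewide
birth cohort plus its hospital files: per-delivery demographics drawn
from marginal tables (payer, race/ethnicity, education, maternal age),
gestational-age strata with ~89% term births, a ~3% twin rate, fetal
deaths at ~0.55% of deliveries (which produce no infant episode),
per-condition prevalences recorded independently on each source with
source-specific sensitivities (the mechanism that makes dual-source
ascertainment informative), encrypted SSNs on ~80% of maternal and ~5% of
infant episodes, episode withholding (the reason real linkage rates sit
near 90% rather than 100%), optional payer-differential withholding for
selection-bias experiments, and an independent per-field error model
(DOB transposition, field deletion, zip typos) that exercises every
comparator branch. ICD codes are written consistently with the generated
truth, so indicator derivation inverts the generation exactly on
unperturbed episodes; every probability is always consumed from the RNG
stream, so cohorts generated at different error levels from one seed are
coupled (lower-level perturbations are a subset of higher-level ones).

What it does *not* emulate — and therefore what passing tests cannot
show about real data: realistic geography or hospital volumes, secular
trends, correlated field errors (a self-pay record is no likelier to have
a bad DOB unless configured), native restricted-file layouts, clerical
miscoding of clinical ICD codes, and out-of-hospital births. Indicator
codes for one delivery are also written symmetrically to the maternal and
infant episodes so that every comparator can fire on both sides, which is
a simplification of real coding placement.

The ascertainment condition groupers beyond the scoring
table's own code lists (eclampsia, abruption, chorioamnionitis, the birth
defects, and so on) are editable defaults — a reasonable reading of
obstetric coding practice, not a validated published grouper — and are
flagged as such in the packaged config.

## Numerical and reporting conventions

- Percentages are reported to two decimals with round-half-up (decimal
  arithmetic, not binary floats); counts are never rounded; undefined
  ratios (zero denominators) surface as explicit nulls, never 0.
- Dates are ISO-8601; the missing token in CSV files is the empty string;
  zips are strings (leading zeros survive round trips).
- A DOB transposition is only applicable when day ≤ 12 and month ≠ day;
  the generator logs inapplicable draws rather than silently skipping.
- Truth-based evaluation counts an infant assignment as correct when it
  lands on any episode in the record's exchangeable set: same-sex
  multiples whose hospital records agree on sex, birthweight band,
  delivery mode, and survival are impossible for *any* algorithm to tell
  apart, so either assignment is scored as correct (and such assignments
  are flagged as tie-broken in the output).

## Verification design and problem sizes

The acceptance boundary sweep enumerates concordance patterns exhaustively
over one representative level per distinct point value (levels sharing a
point value are interchangeable for totals and acceptance), confirming
that the minimum accepted maternal score is exactly 40 and the infant
minimum exactly 31. Engine behavior is checked against an exhaustive
all-pairs score-filter-select oracle on 50 random instances of ~120
deliveries; these instances perturb one blocking key at a time (DOB
transposition plus episode withholding), because a pair carrying *both* a
transposed DOB and a deleted or miskeyed zip retains no exact blocking
key in any pass — such pairs are unreachable by the multi-pass design
itself (a documented recall cost, regression-tested as such), not by a
defect in candidate generation or selection. Perfect-data recovery is
demonstrated at 10,000 deliveries with the error model disabled;
determinism and degradation monotonicity run at 400–2,500 deliveries with
three replicate seeds. These sizes were chosen to keep the full suite
comfortably under a couple of minutes while leaving every check
statistically meaningful.

## Known limitations

- Greedy contention resolution is not a global maximum-weight assignment;
  on adversarial instances a contested episode can cascade into a
  different link set than the optimum. With realistic data the two agree
  (the oracle equivalence above), because true counterparts dominate
  their false rivals.
- Compound perturbations (transposed DOB plus missing/erroneous zip) make
  a record unreachable by every blocking pass even though its score would
  clear the cutoff — the recall ceiling of blocking designs generally.
- Post-discharge episodes of the *same* infant can absorb the principal
  link when the true birth record's DOB is perturbed out of pass A; the
  link is to the right person but the wrong episode, and it is counted as
  an error by the truth metrics.
- The no-SSN longitudinal path is a person-level demographic score; with
  sparse demographics it will under-attach rather than over-attach, by
  construction of the DOB requirement.
- Fixed comparator weights cannot adapt to local data quality the way
  EM-estimated weights would; that trade (auditability for adaptivity) is
  inherent to the method.
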