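# vitalink

Linkage of vital-statistics birth and fetal-death certificate records to
hospital discharge records for the birthing person and the infant, using a
deterministic/probabilistic hybrid: blocking passes to generate candidate
pairs, an additive link score to rank them, and hard eligibility rules to
keep only trustworthy links. The package is aimed at perinatal
epidemiologists who build or audit maternal–infant linked cohorts from
administrative files, and at methodologists who want to study how linkage
design choices propagate into selection bias. Because the statewide source
files such pipelines run on are restricted, the package also ships a
ground-truthed synthetic cohort generator that emulates their statistical
structure, so the whole method is exercisable, testable, and auditable
without any protected data.

## The method

Each certificate record *v* is compared to each candidate hospital episode
*e* on up to 18 variables (dates of birth, hospital, zip, county, payer,
race and ethnicity, infant sex, gestational-age band, birthweight band,
plurality, delivery mode, maternal comorbidities, infant death). Every
variable *k* contributes fixed points at the concordance level it reaches,
and the link score is the sum

&nbsp;&nbsp;&nbsp;&nbsp;S(v, e) = Σₖ wₖ(levelₖ(v, e)),&nbsp;&nbsp;0 ≤ S ≤ 148,

with, for example, w = 10 for an exact date-of-birth match and 5 when month
and day are transposed, 20 for concordant gestation under 29 weeks, and
10 + 5·[minority] or 10 + 2·[White] for a race match. Clinical variables on
the hospital side are derived from ICD-9/ICD-10 code-prefix sets. A
maternal link requires the mother's date of birth (transposition or a
differing year tolerated), the infant's date of birth, and the hospital to
link, plus at least one other variable, plus S ≥ 40; an infant link
requires concordant infant sex plus S ≥ 31. Candidates are generated by
six maternal and nine infant blocking passes over different exact-agreement
key pairs, removing linked records between passes; per record the
highest-scoring accepted candidate wins, with exact ties broken uniformly
at random under a seeded, record-keyed RNG. Multiple-gestation deliveries
may share one maternal episode when both sources classify the birth as a
multiple birth; field-identical same-sex multiples are assigned at random
and flagged. A longitudinal step then attaches further hospital/ED/
ambulatory-surgery episodes within one year of delivery (birth to one year
for infants), requiring an encrypted-SSN match *plus* at least one other
variable, or a person-level demographic score when no SSN is available.

## Worked example

```python
from vitalink import (SimulationConfig, LinkageConfig, simulate_cohort,
                      link_all, linkage_rates, truth_metrics,
                      ascertainment_union)

sim = SimulationConfig(n_deliveries=5000, rng_seed=11)
vitals, mother_eps, infant_eps, truth = simulate_cohort(sim)
result = link_all(vitals, mother_eps, infant_eps, LinkageConfig(rng_seed=11))

m = linkage_rates(result, vitals)
print(f"linked to birthing person: {m.n_linked_mother} ({m.rate_mother}%)")
print(f"linked to infant:          {m.n_linked_infant} ({m.rate_infant}%)")
print(f"linked to both:            {m.n_linked_both} ({m.rate_both}%)")
tm = truth_metrics(result, truth)
for side in ("mother", "infant"):
    print(f"{side}: precision={tm[side]['precision']:.4f} "
          f"recall={tm[side]['recall']:.4f}")
row = ascertainment_union(result, vitals, mother_eps + infant_eps,
                          "gestational_diabetes")
print(f"gestational diabetes: certificate {row.pct_vs}%, "
      f"hospital {row.pct_hospital}%, either {row.pct_union}%")
```

prints

```
linked to birthing person: 4718 (92.27%)
linked to infant:          4846 (94.78%)
linked to both:            4475 (87.52%)
mother: precision=1.0000 recall=0.9998
infant: precision=0.9959 recall=0.9955
gestational diabetes: certificate 4.16%, hospital 7.62%, either 8.11%
```

Of the 5113 simulated live births, 92.27% link to a maternal delivery
episode and 87.52% to both sides — the shortfall is dominated by episodes
the generator deliberately withheld (records with no counterpart to find).
Against the generator's truth table, essentially every link made is
correct (precision ≈ 1) and essentially every findable counterpart is
found (recall ≈ 1); residual infant-side errors come from records whose
perturbed fields leave no exact blocking key. The ascertainment row shows
the motivating payoff of linking at all: querying certificate *or*
hospital record captures roughly twice as many gestational-diabetes cases
as the certificate alone.

The same pipeline is scriptable from the shell:

```bash
vitalink run --seed 11 --outdir out/          # simulate → link → evaluate
vitalink report --metrics out/metrics.json    # text tables on stdout
```

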