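# Additive link-score point table: one block per comparator variable,
# mapping each named concordance level to its point value.  The shipped
# values give a per-variable-maximum sum of 148 (the attainable score
# range is 0-148); override for sensitivity analyses.
mother_dob:        {exact: 10, transposed: 5, year_differs: 0}
hospital:          {exact: 10}
infant_dob:        {exact: 10, transposed: 5}
zip:               {exact: 5}
ga:                {lt29: 20, 29to36: 10, 37to42: 2, gt42: 10}
sex:               {exact: 2}
payer:             {exact: 5}
race:              {minority: 10, white: 7, match: 5}
ethnicity:         {exact: 2}
county:            {exact: 2}
infant_death:      {exact: 10}
cesarean:          {exact: 5}
previous_cesarean: {exact: 10}
birthweight:       {lt2500: 10, 2500to4499: 2, ge4500: 10}
sga_lga:           {exact: 7}
hypertension:      {exact: 10}
diabetes:          {exact: 10}
plurality:         {singleton: 2, multi: 10}
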