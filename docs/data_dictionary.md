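# Data dictionary

Columns of the plain-CSV artifacts a pipeline run writes. All dates are
ISO-8601; missing values are empty cells.

## trial_register.csv (one row per randomised participant)

| column | meaning |
|---|---|
| participant_id | opaque unique study id (`T#####`) |
| trial_id | NEP, NETSGA, LCPUFAP, LCPUFAT, IRONT, PALMT, NUCLEOT |
| arm | `modified` or `standard` formula |
| centre | recruitment centre code |
| randomisation_date | date of randomisation |
| dob | date of birth |
| sex | 1 = male, 0 = female |
| birth_weight | grams |
| gestational_age | completed weeks |
| maternal_age | years |
| maternal_smoking | mother smoked during pregnancy (0/1, may be missing) |
| maternal_degree | mother holds a degree (0/1, may be missing) |
| death | died in infancy (0/1) |
| death_date | date of death where death = 1 |
| twin_group | shared id for twin/triplet sets, empty otherwise |
| forename, surname | identity as recorded at enrolment |
| true_pupil_id | ground-truth register pupil (simulation only; empty if absent) |

## trial_contacts.csv (one row per identifier contact)

participant_id, contact_date, forename, surname, dob, postcode — the
transcribed identifier history; corruptions from the error model appear
here.

## pupil_register.csv (one row per register pupil)

| column | meaning |
|---|---|
| pupil_id | register person id (`P######`) |
| sex, dob, forename, surname | current identity |
| in_state_census | 0 = reachable only via exam records (no census identifiers) |
| ks2_year, ks2_maths, ks2_english | age-11 assessment year and raw scores (0–100) |
| gcse_year | GCSE examination year |
| gcse_maths … gcse_dt | letter grades A*–G/U per subject, empty if no record |
| sen_ever | ever flagged for special-educational-needs support (0/1) |

## pupil_census.csv (one row per identifier-history segment)

pupil_id, census_year, forename, surname, dob, postcode — a new row per
recorded change of identity or address.

## truth_links.csv

participant_id, pupil_id — the ground-truth link (empty pupil_id for
deceased or register-absent participants). Simulation only.

## postcode_lookup.csv

postcode, authority, neighbours (pipe-delimited neighbouring-authority
codes; the relation is symmetric).

## candidates.csv / links.csv

`candidates.csv`: participant_id, pupil_id, per-field agreement levels
(`surname_level`, `forename_level`, `dob_level`, `postcode_level`),
Fellegi–Sunter `score` (log2 units), `n_exact`, per-participant `rank`
and `margin` (score gap to the runner-up). `links.csv`: one decision
per participant — pupil_id (empty if unlinked), status
(`linked`/`unlinked`/`excluded_death`), score, margin.

## analysis_dataset.csv (one row per randomised participant, ITT)

Baseline columns as in trial_register plus: linked (0/1), pts_maths16 /
pts_english16 (grade points), sd_* (within-trial z-scores at 16 and 11),
ext_maths16 (externally standardised), five_plus_gcse_c, sen_ever.

## estimates.csv / power.csv

`estimates.csv`: trial_id, outcome, analysis_label (MI_adjusted,
MI_unadjusted, CC_adjusted, CC_unadjusted, external_standardised),
estimate (SD units; log-odds for binary outcomes), se, ci_low, ci_high,
m, W (within-imputation variance), B (between), n, status, robust.
`power.csv`: trial_id, n1, n2 (analysable per-arm counts), mdes.
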