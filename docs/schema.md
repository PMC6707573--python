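# Trial CSV schema

Wide format: one row per participant, UTF-8, header row. Empty cell =
missing (never 0). Unknown columns are ignored with a warning. The full
column list is available programmatically as `trialcea.trial_data.TRIAL_COLUMNS`.

## Identity

| column | type | notes |
|---|---|---|
| `id` | string | mandatory, unique participant id |
| `arm` | `ISMI` or `WLC` | mandatory |
| `gross_monthly_wage` | EUR/month, ≥ 0 | used for productivity costing |

## Scores (per timepoint `T1` week 0, `T2` week 7, `T3` week 26)

| column | type | notes |
|---|---|---|
| `pss_T1`, `pss_T2`, `pss_T3` | integer 0–40 | `pss_T1` mandatory; strict validation requires `pss_T1` ≥ 22 |
| `sf6d_T1..T3` | real 0–1 | SF-6D utility |
| `eq5d_T1..T3` | real −0.59–1 | EQ-5D-3L utility (may be negative) |

A missing `pss_T3` marks the participant as a dropout.

## Resource use (per recall window suffix `_W1` baseline, `_W3` follow-up)

All counts ≥ 0 over the 3-month window. A fully empty window (all cells
blank) means the window is missing and must be imputed.

| column stem | unit |
|---|---|
| `physician_contacts`, `specialist_contacts`, `psychological_contacts`, `allied_health_contacts` | contacts |
| `inpatient_days` (≤ 92), `semiresidential_days`, `rehabilitation_days` | days |
| `prescriptions` | encoded list `drug:packages;drug:packages` |
| `otc_spend` | EUR out of pocket |
| `travel` | encoded list `mode:value;...` — `car:` round-trip km, `bus:`/`taxi:` fare EUR |
| `waiting_and_treatment_hours` | hours |
| `informal_care_hours` | hours |
| `absence_days`, `impaired_days` | workdays |
| `inefficiency_score` | real in [0,1] |

# Unit-cost CSV schema

Columns `category, unit_price_eur, unit`. Category rows set per-unit
tariffs (`physician_contact`, `specialist_contact`,
`psychological_contact`, `allied_health_contact`, `inpatient_day`,
`semiresidential_day`, `rehabilitation_day`); rows named after a costing
constant (`car_km_rate`, `opportunity_rate`, `informal_care_rate`,
`intervention_price`, `price_index_factor`, `ppp_eur_to_usd`,
`statutory_share`) override that constant. Anything omitted keeps the
built-in 2013 defaults.

# Drug-price CSV schema

Columns `drug, pack_size, statutory_price_eur, private_price_eur`, one row
per package; read with `trialcea.costing.read_drug_prices`.
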