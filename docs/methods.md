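# Methods

## Study design assumed by the pipeline

The pipeline implements an economic evaluation alongside a two-arm
randomized trial: participants randomized 1:1 to a guided internet-based
stress-management intervention (ISMI) or a waitlist control (WLC) with
unrestricted usual care, assessed at randomization (T1, week 0), post
treatment (T2, week 7) and 6-month follow-up (T3, week 26). Costs are
taken from the societal perspective over a 6-month horizon, so no
discounting is applied. Resource use is self-reported over two 3-month
recall windows (W1 before baseline, W3 before follow-up), TiC-P style.
Weeks convert to years at exactly 52 weeks/year so that week 26 = 0.5
years and full health over the horizon accrues exactly 0.5 QALY.

## Costing

Every recurring category is units × unit price in 2013 euros. Specifics:

- **Medication.** A drug's unit price is the mean per-package price of its
  up-to-3 largest packages, computed separately for statutory and private
  insurance and weighted by the statutorily insured population share
  (0.888). The national price register is replaced by a configurable table
  (`costing.DrugPriceTable`); the shipped default is a small synthetic
  table used by the generator and examples.
- **Productivity.** Absenteeism uses the human capital approach: work-loss
  days × gross daily wage, with daily wage = monthly wage / 21.67 workdays
  (260 working days / 12 months; the divisor is a package choice, as only
  "average gross daily wage" is specified by the costing convention).
  Presenteeism uses the Osterhaus method: impaired days × inefficiency
  score (stored normalized to [0,1]; divide a raw 0–10 instrument score by
  10 at ingest) gives lost-workday equivalents, valued at the same daily
  wage.
- **Opportunity costs** (€23.10/h) apply to waiting/treatment time only;
  time spent using the intervention itself is treated as leisure and not
  costed.
- **Cumulation.** The 6-month figure per category is the trapezoid between
  the two 3-month window rates: (W1 + W3)/2 × 2. The baseline window
  serves as the month-0 rate anchor. An alternative rule that
  extrapolates the follow-up window alone (`auc_mode="double_followup"`)
  is selectable, since the anchor choice is a genuinely open design point.
  The €299 intervention tariff is a one-off added once to the treatment
  arm's 6-month total, never interpolated.
- **Rounding and currency.** All computation is at full float precision;
  rounding (half-up) to whole euros happens only at reporting. The
  per-category report table rounds each mean independently and rounds the
  total of the *unrounded* means, so components need not sum to the total.
  US dollar figures use the 2013 purchasing power parity €1 = US $1.29.

## Outcomes

Symptom-free status is PSS-10 at follow-up strictly below baseline mean −
2 SD = 25.52 − 2·3.91 = 17.70; with integer PSS scores the strict/
non-strict boundary choice is immaterial (scores ≤ 17 qualify). It is
computed on imputed scores (intention to treat). QALYs are trapezoidal
areas under the utility curve with *no* baseline adjustment (baseline
utilities are balanced by randomization in the emulated design); a
regression-based adjustment is deliberately not applied by default.

## Missing data

Dropout (missing follow-up assessment) removes T2/T3 outcomes and the W3
recall window. Clinical outcomes get multiple imputation with m = 10: for
each incomplete column a normal linear model on the baseline predictors
(arm, baseline PSS, baseline SF-6D, baseline window total cost, wage) is
fit on observed rows; each completed copy uses a fresh posterior draw of
(σ², β) — σ² from its scaled inverse-χ² marginal, β | σ² from
N(β̂, σ²(XᵀX)⁻¹) — plus residual noise, clamped to the instrument range
(PSS rounded to integers). This proper-imputation scheme approximates an
MCMC multivariate-normal imputation: both draw from a multivariate normal
posterior approximation. Costs get single regression imputation at the
window × category aggregate level: deterministic OLS predictions on arm,
the category's baseline-window cost, baseline total cost and wage, floored
at 0; a singular design falls back to arm means with a logged warning.
Observed values are never altered.

Pooling: point estimates are computed per completed dataset and averaged;
bootstrap draws are stacked equally (round-robin) across the m completed
datasets. Imputing once per bootstrap replicate is *not* done — impute
first, bootstrap after. This is the simpler, common ordering; variance
pooling by combination rules is not needed because inference is
bootstrap-percentile based throughout.

## Decision analysis

The cost and effect equations are regressed jointly on an intercept and
the arm indicator. With identical regressor sets the seemingly-unrelated-
regression estimator coincides with equation-by-equation least squares, so
the incremental estimates equal the arm-mean differences exactly; the
cross-equation residual correlation is reported (0 when a residual
variance is 0). The bootstrap (default B = 5000) resamples participants
with replacement *within arm*, preserving the 132/132 design. Resample
indices depend only on (arm sizes, B, seed), so scenario variants run with
the same seed pair draw-for-draw — the ±€100 intervention scenarios shift
every incremental-cost draw by exactly ±100.

- **ICER.** ΔE > 0 with ΔC < 0 is "dominant", ΔE < 0 with ΔC > 0
  "dominated"; ΔE = 0 is undefined and raised, never a silent NaN. For
  the interval, a ratio whose cloud spans quadrants has no well-defined
  CI, so the convention is: lower end "dominant" whenever south-east draws
  exist; upper end = 97.5th percentile of the ratios among north-east
  draws ("dominant to X"); all ends dominant when no north-east draws
  exist.
- **Plane.** Quadrants by sign of (ΔE, ΔC); boundary draws go to the
  positive-effect side (ΔE = 0 counts east) and zero-cost draws count
  south, each draw counted once, so shares always sum to 100%.
- **CEAC.** P(cost-effective at λ) = share of draws with λ·ΔE − ΔC > 0.
  Default grids: €0–5000 step 100 for symptom-free status and PSS points;
  €0–50,000 step 500 for QALYs.
- **Symptom-free effects** are analyzed as linear probability differences
  (the 0/1 indicator entered in the least-squares effect equation).
- **Scenarios:** `main`, `no_inpatient` (inpatient category zeroed),
  `intervention_plus_100` / `intervention_minus_100`, and `eq5d` (QALYs
  from the EQ-5D-3L column).

## Synthetic trial generator

The generator emulates the *marginal* structure the analysis assumes, not
any real trial's joint distribution: baseline PSS from N(25.52, 3.91)
truncated below at the inclusion cutoff 22 (rounded to integers); follow-up
PSS = baseline − improvement + N(0, 6), clamped to [0, 40], with mean
improvement 9.75 (ISMI) vs 3.0 (WLC) and 80%/30% of it realized at week 7;
SF-6D utilities mean 0.65 (SD 0.11 ISMI / 0.08 WLC) and EQ-5D mean 0.56
(SD 0.10), each coupled to the concurrent PSS z-score through a Gaussian
copula (default correlation −0.4, a mild coupling consistent with a clear
clinical effect but a small utility effect; the true dependence is
unknowable from summary statistics). ISMI utility gains of +0.015/+0.025
(T2/T3) imply an expected QALY difference of ≈0.008; the EQ-5D gains
+0.003/+0.006 imply ≈0.002.

Resource-use quantities are zero-inflated lognormal per category, in
natural units per window, parametrized by (zero probability, positive-part
mean, log-scale). Defaults are calibrated loosely to the magnitude of
published per-category cost means for this population (e.g. ≈3.5 physician
contacts/window at €20, ≈15 informal-care hours at €18.33, ≈5 absence
days against a lognormal wage with median €3000/month); inpatient
admissions hit 3.4% of participants once, in a random window, with
lognormal length-of-stay (mean 7 days at €550/day). Counts are left
continuous (not rounded) so the generator's closed-form moments in
`expected_summaries` are exact, which is what the parameter-recovery tests
compare against; validation only requires nonnegativity. The intervention
effect on costs is a multiplicative reduction of selected follow-up-window
quantities in the ISMI arm (psychological contacts ×0.40, informal care
×0.50, absence days ×0.70, impaired days ×0.75, waiting hours ×0.85),
chosen once so the expected total incremental cost is moderately negative
net of the €299 tariff. The inefficiency score is Beta(2, 5) (right-skewed
on [0,1]; the instrument's distribution is otherwise unspecified). Dropout
is 12.8% (ISMI) / 8.33% (WLC), independent of everything else (MCAR),
deleting T2/T3 outcomes and the W3 window.

What passing tests therefore show: the machinery is correct under MCAR
dropout, Gaussian-copula utility coupling and independent zero-inflated
lognormal costs. Real trial data have informative dropout, correlated
resource-use categories and heavier cost tails; results there inherit the
usual caveats of regression imputation and bootstrap percentile intervals.

## Problem sizes and numerical choices

Unit and acceptance tests run the generator at 20/arm for interface
checks and 2000/arm for moment-recovery checks with B = 1000 bootstrap
draws; Monte-Carlo assertions use a 3·SE tolerance with fixed seeds. The
full-scale worked example (132/arm, B = 5000, m = 10) runs in about two
seconds. Seed handling: one top-level seed spawns independent per-stage
seeds (generation, imputation, bootstrap) via a seed sequence, each kept
below 2³¹; identical configuration and seed reproduce every output file
byte-for-byte.

## Known limitations

- No variance pooling across imputations by combination rules (by design:
  percentile-bootstrap inference).
- The drug price table is synthetic; users must supply real package prices
  for substantive medication costing.
- Utility scoring from raw questionnaire items is out of scope; utilities
  enter as numbers.
- The CEAC conditions on the pooled (stacked) bootstrap cloud rather than
  per-imputation curves.
- A single price-index factor (1.04, to 2013) and a single PPP rate (1.29)
  are supported.
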