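# Methods

## Evidence synthesis

Each randomized trial compares one MIGS device implanted during cataract
surgery against cataract surgery alone, reporting per-arm mean (SD) IOP at
baseline and one year.  The single efficacy endpoint is the one-year change
from baseline, follow-up minus baseline, so negative values are reductions.

Because the published summaries omit arm sizes and change-score SDs, the
change-score SD is reconstructed as
`sd_Δ² = sd_b² + sd_f² − 2·ρ·sd_b·sd_f` with a default baseline–follow-up
correlation of ρ = 0.5 — the conventional conservative choice — configurable
per trial; SEs exist only when an arm size (or an external per-trial SE) is
supplied.  Pooling across trials of one device uses inverse-variance weights,
DerSimonian–Laird random effects by default (fixed effects behind a flag),
with `Q`, `τ²` and `I² = max(0, 100·(Q − (k−1))/Q)` reported; when SEs are
unavailable the pool degrades to an unweighted mean of point estimates and no
interval is produced.  The packaged one-TMBS pool is therefore −1.35 mmHg
relative to cataract surgery, slightly different from the published −1.10,
whose inverse-variance weights cannot be recovered from the printed tables;
nothing downstream asserts that value.  Device-class arms ("one or two TMBS",
"MIGS as a class") pool the member trials' relative effects before anchoring.

Anchoring follows the adjusted indirect comparison: the pooled relative
effect is added to the absolute change under the common comparator, and
variances are summed under the independence assumption.  The comparator
change, −2.05 mmHg (95% CI −3.38 to −0.72), is taken as a configured input
rather than re-pooled, since pooling the four control arms would again
require the unpublished weights.

## Disease model

Five states: early, moderate, advanced POAG (Hodapp–Parrish–Anderson staging
by visual-field mean deviation, −6 and −12 dB thresholds; blindness at
deviation ≥ −22 dB), blindness and death.  The cohort starts at age 63,
44.2% female, all in early disease, and runs in yearly cycles to age 110 or
extinction.  Within each cycle, death (the sex-mix-weighted life-table
probability at the cohort's current age) is resolved first and the survivors
then stay or progress one stage; the order matters in the third decimal and
is fixed here because the alternative is equally defensible.  There are no
backward transitions, blindness is absorbing except for death, and mortality
is state-independent (no published excess hazard for blindness).

Annual progression probabilities for standard of care are 8.5%, 12.4% and
18.6% (early, moderate, advanced), derived upstream from 5-year observational
percentages via `p₁ = 1 − (1 − p₅)^(1/5)`; that conversion is available as a
utility and round-trips exactly.

Each mmHg of extra IOP reduction improves the visual field by 0.31% per
year.  How the original analysis turned that slope into transition
probabilities is not recoverable, so two mappings are provided and the choice
is a config field:

* **multiplicative on the rate** (default): `r = −ln(1 − p)`,
  `r′ = r·(1 − 0.0031)^δ`, `p′ = 1 − e^(−r′)`.  Preserves [0, 1], reduces to
  identity at δ = 0, composes sensibly in δ.
* **linear on the rate**: `r′ = r·(1 − 0.0031·δ)`, clamped at zero with a
  warning.

The default yields incremental QALYs of a few thousandths — the same order
as the reference lifetime results — but absolute ICER levels inherit the
mapping uncertainty and should be read as ordering/magnitude statements.

The effect (and the one-off intervention cost) attaches to cohort mass at its
first arrival in the application stage — moderate or advanced, both are run —
and the slowing then applies to that stage and every later stage; in a
strictly forward model this per-entry accounting is exactly equivalent to
applying the multiplier to all stages at or past the application stage in
every cycle.  The one-year effect is assumed constant for the remaining
lifetime, consistent with the lifetime-horizon framing of the reference
results; no waning is applied by default.

## Economics

Utilities: 0.85, 0.75, 0.58 for the three POAG stages; blindness is
extrapolated by OLS through (stage index, utility) evaluated one stage
further, 0.4567 ≈ 0.46 at the reported 2-decimal rounding.  Annual stage
costs (2019 EUR) are recomputed from their components (323.19, 356.13,
513.42; the source prints the moderate total as 356.12, a 1-cent rounding
artifact — the fixture stores components only).  The printed SD "totals" are
the linear sum of component SDs and are reproduced as such; SDs
parameterize the probabilistic analysis only and never enter deterministic
results.  The cost table has no blindness row; by default blind patients keep
consuming at the advanced-stage level (they remain under medication and
follow-up), overridable via `blind_cost`.  Intervention totals: cataract
alone €224.84; one device + cataract €638.42; two devices + cataract €937.34.
Class arms use the trial-count-weighted mean of member device costs, a
package choice where the source is silent.

Payoffs accrue at cycle start (a half-cycle switch exists, default off, since
the source describes none) and are discounted at 3%/year after year one for
both costs and effects.  ICERs are increment quotients with
dominant/dominated/equivalent labels when the increments disagree in sign.
Monetary outputs are rounded to 2 decimals at report time only.

## Sensitivity analyses

**One-way (tornado):** every registered parameter — stage progression
probabilities, stage utilities and costs, the IOP effect, intervention and
reference costs, the discount rate — is set to ±20% of base with the rest
fixed; probabilities and utilities are clamped to their domains with a
warning, infeasible scenarios are recorded as failed rather than dropped,
and results are ranked by ICER spread.  At base case the moderate-stage
utility, blindness utility and the IOP effect rank among the most
influential inputs, and procedure costs less so.

**Probabilistic:** beta for utilities and transition probabilities, gamma
for annual costs, normal for the IOP effect, all moment-matched from
mean/SD.  Effect SDs come from the published anchored intervals via the
Bucher variance difference; transition probabilities have no published SD
and default to 10% of the mean.  Parameters are sampled independently (no
published correlation structure); one master seed spawns a name-keyed stream
per parameter, so adding a parameter never reshuffles the others' draws.
Draws are shared between the comparator and reference arm within an
iteration, so uncertainty common to both cancels in the increments.  An
infeasibly large beta SD is shrunk to feasibility with a warning.  The CEAC
counts an iteration cost-effective at threshold λ when `inc_qaly > 0` and
`inc_cost ≤ λ·inc_qaly`.

## Synthetic data

The life table is Gompertz–Makeham, `q(age) = 1 − exp(−∫(a + b·e^{c·x})dx)`
per sex with a ×1.6 male hazard excess and certain death at 110.  Defaults
(a = 4·10⁻⁴, b = 6.7·10⁻⁶, c = 0.11) give remaining life expectancy at 63 of
22.3 years (women) and 18.8 (men), near contemporary German values; the
table is smooth and deliberately does not replicate any official table's
entries.  Simulated trials draw correlated bivariate-normal
(baseline, follow-up) IOP pairs per subject with a known true relative
effect, supporting parameter-recovery tests of the meta-analytic machinery
(the DerSimonian–Laird interval covers the truth at ≈95% over seeded
replicates).  What the generator does not emulate: non-normal IOP
distributions, dropout, measurement rounding, or between-trial heterogeneity
in true effects — so passing recovery tests show correctness of the
statistics, not robustness to those real-data features.

## Numerical choices and problem sizes

Trace rows are validated to sum to 1 within 1e−9 and death occupancy to be
non-decreasing; at zero effect the strategy trace is bit-identical to the
reference (the rate transform short-circuits exactly).  The cohort trace is
cross-checked against a 5,000-individual microsimulation using the same
per-cycle probabilities; because deviations along a trajectory are serially
correlated, agreement is asserted as the bulk of state–cycle cells within
2 Monte Carlo SEs and all cells within a 3-SE envelope (with a 10⁻³ floor
where occupancy is near 0 or 1).  The default PSA uses 10,000 iterations
(seconds of runtime); coverage checks use 500 replicate meta-analyses of
4 trials × 100 patients/arm.  A default full run (evidence synthesis plus
all strategy × stage cohort runs) completes in well under a second.

## Known limitations

* The IOP→transition mapping is a reconstruction; absolute ICER levels are
  several-fold sensitive to it (orderings are stable across the two provided
  mappings).  Consequently the share of PSA iterations under the
  €43,433.87/QALY benchmark is far smaller here (≈0.3) than under the
  original unpublished mapping.
* No re-operation, adverse-event or bilateral-eye modelling; no individual
  heterogeneity in IOP response; no societal costs.
* Star-shaped indirect comparisons only (one common comparator); no network
  meta-analysis or publication-bias diagnostics.
* Results are parameterized for the German setting and do not transfer
  without re-parameterization.
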