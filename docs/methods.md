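# Methods

## Report cleaning

Spontaneous-report databases publish one row per *report version*; a
case that is followed up appears several times under one CASEID with
different PRIMARYIDs and receive dates. Cleaning follows the FDA's
recommended order:

1. **Deduplication** keeps, per CASEID, the version maximizing
   (FDA_DT, PRIMARYID). PRIMARYIDs compare numerically when every id in
   the store parses as an integer, lexicographically otherwise. A
   missing FDA_DT sorts below every real date, so an undated version
   survives only when no dated duplicate exists.
2. **Deletion lists** (published quarterly since 2019Q1) are unioned
   across all supplied quarters and applied *after* deduplication, by
   CASEID. Because deletion is keyed on the case, the final store is the
   same under either order; the implementation nevertheless follows the
   documented order, and a test pins it through the removal accounting.
3. **PT remapping** normalizes reaction preferred terms against a
   caller-supplied `old_pt → (current_pt, soc)` table (MedDRA is
   licensed and cannot be redistributed, so no vocabulary ships with the
   package). Matching trims and case-folds; unmapped terms pass through
   with SOC `UNMAPPED-SOC`.

Drug matching is a case-insensitive substring test on the drug-name
field with an optional synonym list, because FAERS drug strings are
verbatim (brand names, salts, combination products).

## Contingency tables

The counting unit is the **drug–event pair**: each distinct
(report, PT) occurrence counts once, so a report with three reactions
contributes three pairs, and duplicates of one PT within a report
collapse. Under this convention the per-SOC pair counts of a drug sum
exactly to the drug's grand total, which is how published SOC summary
tables total up; SOC-level tables are therefore sums of their PTs' pair
counts (a report with two PTs in one SOC contributes two pairs).

### Reconstructing tables from published statistics

A published signal table usually prints `a`, the ROR with CI, and EBGM,
but not `c` and `d`. Since ROR fixes `d/c` given `(a, b)` and EBGM pins
the absolute scale, the integer background cells are recoverable:
`reconstruct_table_from_stats` scans `c` (default range `[a, 10^6]`),
sets `d = round(ROR·b·c/a)`, and minimizes the summed squared relative
error of the recomputed (ROR, EBGM); ties resolve to the smallest `c`.
When `a` itself is unknown, `reconstruct_table_joint` adds the CI-implied
log-scale standard error `ln(CI_hi/ROR)/1.96 = √(1/a+1/b+1/c+1/d)` as a
third anchor and scans a small grid over `(a, c)`. The recovered tables
are validated by recomputing statistics *not* used in the search (PRR,
χ², CI bounds, shrunk IC bounds) and checking them against the published
values; a round-trip property test (forward statistics → reconstruction)
confirms exact recovery on random tables.

## Disproportionality statistics

Implemented exactly as defined in the README. Numerical notes:

- The CI multiplier is the conventional rounded 1.96 (not Φ⁻¹(0.975)),
  matching how published intervals are computed.
- **χ² flavours.** The Yates-corrected statistic
  `(|ad−bc|−n/2)²·n/((a+b)(a+c)(c+d)(b+d))` (numerator clamped at zero
  when the correction exceeds `|ad−bc|`) drives the Evans PRR rule.
  The uncorrected Pearson statistic is reported alongside it because
  that is what standard pharmacovigilance software prints in signal
  tables: on the reconstructed erectile-dysfunction and haematospermia
  tables the published χ² values (669.285…, 24.639…) are reproduced
  *exactly* by the Pearson form, while the corrected form gives 666.6
  and 21.7. Both are always available on `PrrResult`.
- **BCPNN.** EIC and VIC are the beta-prior posterior moments with
  hyperparameters `α₁ = β₁ = γ₁₁ = 1`, `α = β = 2`; `IC025 = EIC − 2√VIC`.
  On the reconstructed table this reproduces the published IC025
  (1.70281…) to all printed digits, confirming the parameterization.
  Shrinkage keeps `a = 0` estimable; the raw IC is then reported missing.
  EIC → IC as counts grow with fixed proportions (tested at n = 10⁸).
- **EBGM** here is the closed-form observed/expected ratio with a
  log-normal interval — a deliberately simple shrinkage-free variant,
  not the MGPS gamma-Poisson mixture EM fit (whose two-component prior
  would need the full database to estimate). `IC = log2(EBGM)` is exact
  under these definitions and is used as an identity test.
- Any zero cell makes ROR/PRR/EBGM intervals non-estimable; results
  carry an `estimable=False` flag rather than infinities, and never
  classify as signals. No continuity correction is added to the counts
  themselves.
- The PRR positivity rule is not standardized across the literature;
  the Evans rule is the default and the thresholds are configurable
  (`SignalCriteria`). `overall_positive` is the conjunction of all four
  methods' criteria.

## Two-sample Mendelian randomization

- **Instrument selection**: `pval < 5e-8` by default, then greedy
  distance pruning (1 Mb windows, best p first) when positions are
  available. Distance pruning is a stand-in for LD clumping, which needs
  a reference panel and is out of scope; the synthetic generator draws
  independent variants, so pruning there is exact.
- **Harmonization** aligns outcome rows to the exposure's effect allele
  (sign flip on swaps, strand complements accepted), drops palindromic
  A/T and C/G variants by default (their strand is unresolvable without
  allele frequencies), then orients every instrument so `β_x > 0`.
  Wald-ratio SEs use the first-order delta approximation `se_y/|β_x|`
  (second-order available via `second_order_se=True`).
- **IVW** defaults to multiplicative random effects whenever Q/df > 1
  (the common software behaviour — the fixed-effect SE is never
  deflated), with `model="fixed"`/`"random"` switches.
- **MR-Egger** is a weighted least-squares fit (weights `1/se_y²`,
  statsmodels WLS) with the residual scale floored at 1, so
  under-dispersion cannot shrink the SEs; p-values use t with n−2 df.
  Cochran's Q uses the IVW weights about the fitted constant (df n−1)
  or the Egger line (Rücker's Q′, df n−2).
- **Weighted median**: interpolated 50th percentile of the sorted Wald
  ratios at cumulative-midpoint weight positions `(cum_j − w_j/2)/Σw`.
- **Modes**: the maximizer of the normal-kernel density of the ratios
  (unweighted vs IVW-weighted), bandwidth φ × the modified Silverman
  rule `0.9·min(sd, mad/0.6745)·n^(−1/5)` with φ = 1, evaluated on a
  2048-point grid spanning the ratios ±3 bandwidths (tests compare
  against a 200 001-point grid oracle).
- Median/mode SEs come from a parametric bootstrap (5 000 resamples by
  default, seeded; the seed is recorded in pipeline metadata). p-values:
  normal for IVW/median, t(n−2) for Egger, t(n−1) for modes.
- ORs are `exp(β)`. For a binary exposure coded as medication use, β is
  per unit log-odds of exposure — an uninterpreted but conventional
  scale for drug-use instruments.

Published MR estimates for the motivating drug–outcome pair depend on
restricted biobank summary data and unstated clumping defaults, so the
MR arm is validated by **oracle equivalence** (normal-equations WLS,
interpolated weighted quantile, kernel grid search, all re-implemented
from scratch in the tests) and **parameter recovery**: over 200 seeded
replicates of the default scenario (30 instruments, true β = 0.5,
balanced pleiotropy sd 0.02), mean IVW bias is required `< 0.02` with
95% CI coverage in [0.90, 0.99]; with directional pleiotropy (mean 0.05)
the Egger intercept must recover it within 3 Monte-Carlo SEs; under
homogeneity the Q test's 0.05-level rejection rate must sit inside the
binomial 95% band.

## Synthetic data: what it does and does not emulate

**Reports.** Each of 10 000 reports (default) carries one drug drawn
from a nine-drug catalog (target drug probability 0.10) and a set of
PT reactions drawn independently per PT from a 15-term catalog spanning
11 SOCs, with at least one reaction forced (empty reports are invalid).
Implanted signals multiply the conditional event probability — default:
relative risk 4 for the target drug and erectile dysfunction, giving an
expected `a` of ≈ 40 at the default size, large enough for all four
statistics to be estimable yet small enough to remain realistic for a
reproductive-system PT. Truth records carry the expected 2×2 table of
every implanted signal computed analytically from the exact sampling
scheme, conditional on the realized per-drug survivor counts, so
observed tables deviate only by event-draw noise. Cleaning artefacts
are planted at known rates: 5% of cases get a superseded earlier-dated
version under a second PRIMARYID, 2% are flagged on the deletion list,
and 30% of reactions with a legacy spelling are written in it (the
generated `pt_remap.tsv` maps them back). Demographics (age-bin mix with
37% unspecified, reporter types, top-5 countries, 85.5% serious) follow
the published profile of statin-ED reports; receive dates are uniform
over 2004–2023 and onset days come from a mixture with most mass in
0–30 days and a secondary mode at 181–360. *Not* emulated: drug–drug
co-reporting, verbatim drug strings, indication semantics, reporting
trends over time — so passing tests demonstrate correctness of the
statistical machinery, not robustness to every FAERS data pathology.

**GWAS.** Per variant, a true exposure effect γⱼ ~ N(0.2, 0.05²), an
observed `β_x = γ + N(0, se_x²)` with `se_x = 0.01` (strong instruments:
all default variants pass 5×10⁻⁸), and an outcome effect
`β_y = β·γ + α + N(0, se_y² + het_sd²)` with `se_y = 0.05`, pleiotropy
α ~ N(pleiotropy_mean, pleiotropy_sd²) and het_sd modelling
heterogeneity unacknowledged by the reported SE. 20% of outcome rows are
emitted allele-swapped (beta negated) to exercise harmonization.
Variants are independent — there is no LD — so distance pruning and
clumping behaviour on correlated panels is untested by construction.

Both generators are byte-deterministic under a fixed config (golden-file
tests), and all randomness flows from the single config seed.

## Profiling conventions

Age bins are left-closed at 18/45/65/75 (a 45-year-old falls in 45–65);
unknown ages count as "Not Specified" but are excluded from the
mean/median statistics. Onset is the report receive date minus the
earliest therapy start for the target drug — receive date is used
because spontaneous reports carry no reliable event-onset field —
binned {0–30, 31–60, 61–90, 91–180, 181–360, >360} days; negative
onsets are excluded from bins and counted separately. Outcome-code
combinations are reported sorted and semicolon-joined; cases with no
outcome row get an explicit "NOT SPECIFIED" row rather than being
dropped, so the block still sums to the report total. Every emitted
percentage block sums to 100 ± 0.01.

## Problem sizes

The test suite and the acceptance script are desk-scale by design: the
table reconstructions scan ≤ 10⁶ (single) or 200 × 2×10⁴ (joint) integer
candidates vectorized; recovery suites use 200 replicates of 30-variant
GWAS pairs; report-store tests use 10 000-report stores (a few hundred
thousand pairs). These sizes give Monte-Carlo error well inside every
asserted tolerance while keeping a full run under half a minute.

## Known limitations

- EBGM is the closed-form O/E ratio, not an MGPS mixture fit; for very
  small `a` it shrinks less than MGPS would.
- No multiple-testing control across PTs (none is standard in signal
  tables; positives are screening signals, not confirmed ADRs).
- Stratified (age/sex/year) contingency tables, multi-drug adjustment,
  Steiger filtering, MR-PRESSO and multivariable MR are out of scope.
- Disproportionality measures reporting association only; the MR arm
  addresses confounding by indication but inherits its own assumptions
  (relevance, independence, exclusion restriction).
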