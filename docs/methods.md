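# Methods

`pvdisprop` implements disproportionality analysis of spontaneous
adverse-event reports in the FAERS quarterly-ASCII data model: a full
ingestion pipeline (read, deduplicate, join, standardize, select), four
signal-detection estimators on per-term fourfold tables, age-subgroup and
time-to-onset analyses, and a seeded synthetic-data generator that makes
every stage testable against known ground truth.

## Data model and ingestion

A quarter consists of seven "$"-delimited tables keyed by `primaryid`
(report version) and `caseid` (stable case identity): DEMO, DRUG, REAC,
OUTC, RPSR, THER, INDI. The reader matches header names
case-insensitively, keeps all values as strings, counts and skips
malformed rows, and fails only on a missing required column.

**Deduplication.** FAERS distributes every follow-up as a new `primaryid`
under the same `caseid`. One record per `caseid` is retained: the one with
the greatest `FDA_DT`. Ties on the date keep the larger `primaryid` (later
submission); a missing date always loses to a dated record, so the rule is
total and the operation idempotent. Dedup runs across the union of all
supplied quarters, not per quarter. `FDA_DT` (receive date) rather than
`EVENT_DT` orders the versions: the receive date is complete nearly always,
while event dates are frequently missing, and the "most recent report" is a
statement about report versions, not about events.

**Dates.** 8-digit `YYYYMMDD` values are precise; 6-digit `YYYYMM` and
4-digit `YYYY` values are padded with 01 for dedup ordering but flagged
imprecise and excluded from onset computation.

**Age and weight.** Unit codes DEC/YR/MON/WK/DY/HR convert to years
(×10, ×1, ÷12, ÷52, ÷365.25, ÷8766); values outside [0, 120] years are set
missing and counted as anomalies. Weight mirrors this with KG/LBS/GMS and
a [0, 500] kg window.

**Joins.** Reactions, outcomes, drugs, therapy dates and indications
attach by `primaryid` after dedup; rows referencing no surviving report
(including the superseded versions of deduplicated cases) are dropped and
counted as orphans, so the run log's case flow reconciles exactly:
raw rows − duplicates = analyzed cases = target + background. Indication
rows attach to the drug entry with the matching sequence number, falling
back to the case when no drug matches. Reaction terms are deduplicated
case-insensitively within a case.

## Cohort definition

Drug names are standardized by a synonym dictionary matched
case- and punctuation-insensitively as contiguous token subsequences, so
"RINVOQ 45MG TABLET" → upadacitinib but "NOTRINVOQX" does not match. The
shipped dictionary contains the brand and generic names of upadacitinib;
users supply their own YAML for other drugs. A dictionary is transparent
and exactly reproducible, which a statistical name-normalization system is
not; the trade-off is that only listed spellings match.

The target cohort is every case with at least one drug entry that (i)
standardizes to the target drug, (ii) carries role code PS (primary
suspect), and (iii) has a qualifying indication on that drug entry or the
case (default set: ulcerative colitis, colitis ulcerative, Crohn's
disease, inflammatory bowel disease; matching is case-insensitive and the
set is configurable). Everything else is background, so target and
background partition the deduplicated cases.

Age bands are half-open — [0,18), [18,65), [65,∞), unknown — so that a
65-year-old falls in the elderly band, matching the "≥65" convention of
published FAERS subgroup tables.

PT→SOC mapping is a flat two-column lookup (case-insensitive, unmapped →
"Unmapped" with a warning). The bundled table covers the generator's
vocabulary plus a selection of published upadacitinib signal terms; it is
a stand-in for the licensed MedDRA hierarchy, which cannot be
redistributed. Real analyses should supply their own TSV.

**Demographics.** Counts and percentages per factor (year, sex, age band,
country, reporter, serious outcomes). Percentages are rounded half-up to
two decimals. Single-denominator factors divide by cohort size. Serious
outcomes are counted per mention — a case with two outcome codes
contributes to two levels — and their percentages divide by total
mentions, because a case-level partition cannot represent multi-outcome
cases without discarding information. Published tables of this kind are
sometimes internally inconsistent here (summed outcome counts differing
slightly from the implied denominator); this package always reports the
denominator it actually used.

## Disproportionality statistics

For each term t, counts are distinct (case, term) pairs — a case
contributes at most once per term, the standard FAERS convention, since
REAC lists many PTs per case:

|             | term t | other terms |
|-------------|--------|-------------|
| target drug | a      | b           |
| other drugs | c      | d           |

with a+b the target cohort's total pairs and c+d the background's. Two
background modes exist because comparator choice is a genuine design
axis: `rest` (default) uses every non-target case; `same_indication`
restricts the background to cases sharing the indication set, comparing
against the same underlying disease.

With N = a+b+c+d:

* **ROR** = ad/(bc); 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
* **PRR** = [a/(a+b)]/[c/(c+d)]; χ² is the uncorrected Pearson statistic
  (ad−bc)²·N/[(a+b)(c+d)(a+c)(b+d)]; 95% CI on the log scale with
  SE = √(1/a − 1/(a+b) + 1/c − 1/(c+d)).
* **IC** = log₂[aN/((a+c)(a+b))], the information component; interval
  IC ± 2√V.
* **EBGM** = aN/((a+c)(a+b)), the same observed/expected ratio on the
  natural scale, with a log-scale CI using the ROR's SE. No gamma–Poisson
  shrinkage is applied (deliberately out of scope), so **IC ≡ log₂(EBGM)**
  holds identically and is asserted as a cross-check invariant.

**V(IC).** Default mode `delta`: the delta-method variance of the log₂
relative reporting ratio, V = (1/ln 2)²·(1/a + 1/(a+c) + 1/(a+b) − 3/N).
Each reciprocal is ≥ 1/N, so V ≥ 0 on every table, IC025 ≤ IC always, and
IC025 → IC as counts grow. Mode `bate1998` instead uses closed-form
Bayesian posterior moments of the information component with conventional
unit priors; its point estimate shrinks toward 0 for small counts and
converges to the delta-mode value for large ones. The mode used is
recorded with the output.

**Zero cells.** Terms are only analyzed when a ≥ min_a (default 3), so
a > 0 always; if b or c is 0 the Haldane–Anscombe correction adds 0.5 to
all four cells before every statistic and flags the row.

**Signal criteria.** A term is flagged when any of the four rules fires
(configurable to "all"): ROR lower 95% bound > 1 with n ≥ 3; PRR ≥ 2 with
χ² ≥ 4 and n ≥ 3 (the ≥ on PRR is configurable to strict >, as published
threshold statements vary); IC025 > 0; EBGM05 > 2. An undefined statistic
fails its rule rather than erroring.

**Ranking.** Tables sort descending by a chosen statistic (default ROR)
with a deterministic tie-break: larger n first, then term name ascending.

**Subgroups.** The same analysis repeats inside each age band. The
default background is within-group (the band's own non-target cases), the
usual convention in FAERS subgroup analyses; a global-background mode is
available. Empty groups yield an empty table and a warning.

### Known estimator limitations

Two related facts about the unshrunk observed/expected ratio (EBGM/IC)
matter for interpretation and shaped the tests:

* **Self-masking.** The term's own count a enters the margin a+c, so when
  the target cohort is a large share of the database the ratio is biased
  toward 1: approximately r/(1 + t(r−1)) for a true rate ratio r and
  target pair-share t. At t = 10% a true tenfold signal reports as ~5. In
  the intended regime — a single drug in a multi-million-report database,
  t well under 1% — the bias is negligible. Calibration and recovery tests
  therefore run at a ~0.5% target share, the share a real single-drug
  cohort has; the ROR does not suffer from this (its odds construction
  cancels the margins).
* **Non-monotonicity.** For the same reason, IC and EBGM increase in a
  (b, c, d fixed) only while a² < bc; past that point the count inflates
  its own expectation faster than the observed rate. The monotonicity
  property test is restricted to that sparse-signal regime. ROR and PRR
  are strictly increasing in a everywhere.

## Time to onset

Onset is event date minus the earliest precise therapy-start date among
the case's primary-suspect target-drug entries, in whole days. Reports
with a missing or imprecise date on either side, or a negative
difference, are excluded. The summary gives the median and quartiles by
linear interpolation (type 7, numpy's default — an interpolating method is
what fractional published quartiles imply) and counts in bins
[0,30], (30,90], (90,180], (180,365], (365,∞) days, reading "month" as 30
days and "year" as 365. The bins partition [0,∞), so every defined onset
falls in exactly one.

## Synthetic-data generator

The generator emulates the seven-table quarterly structure with fully
known ground truth. Per case it draws: target-drug PS membership
(`target_share`), an IBD indication given that (`indication_share`),
reaction terms from a 27-PT catalog of per-term background probabilities
(mean ≈ 1.75 PTs/case), demographics (sex, age ~ N(47, 17²) clipped to
[1, 95] and encoded in mixed YR/MON/DEC units, country, reporter,
outcomes), report dates uniform over 2019Q3–2024Q1, duplicate re-reports
(same caseid, strictly later date and larger primaryid, identical
content), missing and anomalous ages, missing and month-precision therapy
dates, and onset times from a log-normal (default μ = 3.7, σ = 1.9
log-days, i.e. ~40-day median with a wide right tail, the shape typical
of reported onset distributions).

Planted signals multiply a term's reporting probability by a chosen ratio
inside the target cohort (clamped at 1 with a recorded warning). The
manifest records per-case truth and the realized per-PT (a, b, c, d)
under the same pair-counting rule the analysis uses, so round-trip tests
compare exactly, not approximately. `expected_tables` gives the
closed-form expectations for recovery tests. Everything derives from one
seeded numpy generator: identical config ⇒ byte-identical files.

What the generator does **not** emulate: correlated reactions within a
case, drug–drug masking and competition, reporting-rate drift over time,
real MedDRA vocabulary breadth, name misspellings beyond three fixed
variants, or non-random missingness. Passing tests therefore demonstrate
correctness of the pipeline and calibration of the estimators under clean
conditions, not robustness to every real-data pathology.

### Study sizes used in the statistical tests

* Null calibration: no planted signals, 29,000 cases ≈ 50,000 (case, PT)
  pairs; per-term EBGM means within ±0.1 of 1 and IC means within ±0.15
  of 0.
* Recovery: 470,000 cases at 0.63% target share (cohort ≈ 0.5% of the
  database, the single-drug regime); the ratio-10 term has background
  probability 0.004, so expected a ≈ 100; ROR and EBGM must land within
  ±20% of 10 and the planted term must rank first by ROR.
* Fixture-scale runs elsewhere use 1,200–2,000 cases at 12% target share,
  which keeps the cohort populated at small n.

Seeds are fixed in the tests (0 or small constants chosen up front); the
acceptance script derives all seeds from its `--seed` argument.

## Numerical choices

Percentages round half-up to 2 decimals (matching how published tables
round). Statistics are computed in double precision; the test oracle
recomputes all point values in exact rational arithmetic and requires
agreement to 1e-10 relative error. Degenerate inputs: empty target cohort
→ warning, statistics still defined on whatever terms remain; empty onset
list → error; unknown config keys → configuration error (exit 1); missing
or malformed inputs → data error (exit 2).
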