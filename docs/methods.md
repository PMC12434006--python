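# Methods

## The case/non-case design

Spontaneous reporting systems have no denominators: one cannot
estimate incidence, only *disproportionality* — whether a drug–event
pair is reported more often than the database's margins predict. For
a target drug group and a MedDRA preferred term (PT), the unit of
analysis is the AE record (one REAC row), and the fourfold table is

|                  | target PT | all other PTs |
|------------------|-----------|---------------|
| target group     | a         | b             |
| other groups     | c         | d             |

The comparator is the remaining groups of the six-group study
background (four checkpoint-inhibitor monotherapies, two
combinations), not the full database. This choice mirrors a design in
which every background patient received a checkpoint inhibitor, so
class-typical reporting (e.g. immune-related events) does not inflate
every contrast; a full-database comparator can be emulated by
assigning all remaining cases to additional groups. Descriptive
(baseline) statistics are computed at the patient level; the signal
statistics at the AE-record level.

## Detectors

**Reporting odds ratio.** ROR = (a·d)/(b·c), with the log-scale Wald
95% interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). The normal
quantile is fixed at 1.96. When any cell is zero the Haldane
correction (+0.5 to all four cells) is applied and the result flagged;
the criterion a ≥ 3 makes such corrected tables essentially never
positive.

**Information component.** Two estimators of IC = log₂(observed /
expected) are provided:

* *Gamma-posterior shrinkage* (default). With E = (a+b)(a+c)/N, the
  observed count is modelled as Poisson with a Gamma(0.5, rate 0.5)
  prior on the rate ratio, giving posterior Gamma(a+0.5, rate E+0.5);
  IC = log₂((a+0.5)/(E+0.5)) and IC₀₂₅ is the exact log₂ 2.5%
  posterior quantile via the gamma inverse CDF. The +0.5 shrinkage
  pulls small-count ratios toward independence; IC → log₂(a/E) as
  counts grow.
* *Closed-form BCPNN* (`variant="bate"`). The classical posterior
  mean/variance approximation with beta–Dirichlet priors centred on
  independence (γ₁₁ = α₁ = β₁ = 1, α = β = 2, γ chosen so the prior IC
  is 0), IC₀₂₅ = E[IC] − 1.96·√V[IC]. The two variants agree closely
  for large counts (tested); the default is preferred because its
  lower bound is an exact quantile rather than a normal approximation.

**Joint rule.** A (group, PT) pair is a positive signal iff a ≥ 3,
ROR₀₂₅ > 1 and IC₀₂₅ > 0. Non-computable components (degenerate
tables) never produce a positive flag. Requiring both detectors makes
the rule conservative; its empirical null positive rate on synthetic
independent data is ~2–3% (measured by the acceptance script, not
asserted as a constant).

**p-values and multiplicity.** Each table also gets an independence
p-value — Pearson chi-square without continuity correction, switching
to two-sided Fisher's exact when any expected cell is below 5 (the
method used is recorded per row) — and Benjamini–Hochberg FDR
adjustment. The testing family is all PTs of one drug group, matching
how per-group signal tables are reported. The p-values are
descriptive companions; positivity is decided by the joint rule alone.

## Cleaning

FAERS cases are versioned. Deduplication keeps, per CASEID, the record
maximizing (FDA_DT, PRIMARYID); numeric PRIMARYIDs compare
numerically, non-numeric ones lexicographically after all numeric ones
(determinism). Partial dates order with missing components as zero —
only for this ordering; they never enter day arithmetic. Deletion
lists from all quarters are unioned before removal (a case deleted in
a later quarter must not survive from an earlier one), and removal is
by CASEID after deduplication. DRUG/REAC/OUTC/THER rows are then
restricted to surviving PRIMARYIDs. Each stage logs input/output
counts, producing the filtering funnel on any dataset.

## Cohort assignment

Drug names are matched by case-insensitive substring against a synonym
table (generic + US brand for the four study drugs; longer patterns
first), consulting the active-ingredient field only when the verbatim
name fails. With P the study drugs in PS role and S those in PS-or-SS
role: monotherapy requires P = S = {drug}; a combination requires S to
be exactly the partner pair with the PS drug among them. A study drug
appearing only as concomitant does not alter assignment, and any other
configuration (non-study PS, ≥3 study suspects, no PS record) is
OTHER. Requiring the partner in a *suspect* role is the conservative
reading of dual-therapy membership; the log reports how many
combination cases carried both partners as PS.

## Descriptive statistics

Cramér's V = √(χ²/(N·(min(r,c)−1))) with Pearson chi-square **without
continuity correction** — required to reproduce the published
baseline statistics from their printed counts (e.g. the disability
table gives V = 0.004, p = 0.411 only without correction). Zero
rows/columns are dropped with a warning before computing.

Age is normalized to years (DEC×10, MON÷12, WK÷52, DY÷365.25,
HR÷8766; a missing unit code with age present reads as years, the
dominant FAERS convention) and banded [0,18), [18,45), [45,65),
[65,75), [75,∞). A report is *serious* iff it has at least one outcome
code; each code is also tabulated separately. Onset time is event date
minus the earliest full therapy start among the case's PS-role drug
records; partial dates yield missing. Negative onsets (event recorded
before therapy start; present in real data) are always retained and
flagged in the quantitative block; in the banded table the default
*inclusive* mode folds them into the lowest band while *strict* mode
treats them as missing. Country counts use the occurrence country with
reporter-country fallback.

## Synthetic reporting system

The generator is the package's validation instrument: it emits the
exact dialect the parser reads, plus ground truth. Its defaults are
fixed study conditions, not tuning knobs:

* **Group weights** proportional to the study population's reported
  group sizes (7,386 / 29,544 / 5,278 / 25 / 12,256 / 563 cases),
  scaled into 75% of the database with 25% OTHER (non-study PS drugs).
* **AE records per case** = 1 + Poisson(1.14), matching ≈ 2.14 AEs per
  patient (118,001 records / 55,052 patients).
* **Reaction terms** drawn per case from a 40-PT vocabulary with
  Zipf-decaying baseline rates across 12 organ classes; a planted
  (group, PT, λ) multiplier scales that term's rate within the group,
  renormalized. λ = 1 everywhere gives exact independence, so expected
  ROR = 1 for every pair. Default plants: λ = 5 on cytokine release
  syndrome and λ = 4 / 2.5 on two hepatic/cardiac terms in
  ipilimumab+nivolumab, λ = 4 signals in three other groups.
* **Onset** log-normal with medians 50 d (single agents) / 36 d
  (combinations), σ_log 1.2/1.1, 76% missing (the study's
  missingness); therapy start, event and FDA-receipt dates are mutually
  consistent, with 5% of event dates demoted to year-month to exercise
  partial-date handling.
* **Duplicates**: 17% of cases also emit a superseded earlier version
  (smaller PRIMARYID, earlier FDA_DT), reproducing the ≈ 14.9%
  raw-to-unique drop of the real filtering funnel (removed/raw =
  0.17/1.17); 1% of cases go on the deletion list.
* Demographics (sex, age bands, reporter occupation, countries,
  seriousness, outcome codes, reporting-year profile) follow the
  published baseline distributions of each arm, so the descriptive
  module sees realistic contrasts (e.g. DIG more serious, more
  physician-reported, faster onset).

`expected_table(config, group, pt)` gives the analytic expected
fourfold cells implied by the configuration — the oracle used to test
generator and pipeline jointly (observed cells within 4 SD).

What the generator does **not** emulate: real FAERS drug-name noise
beyond case/brand/strength variants (no misspellings), indication and
dose fields, correlated PTs within a case (draws are i.i.d. given the
group), cross-database duplicate patients under different CASEIDs, and
reporting-rate drift over time. Passing recovery tests therefore shows
the pipeline's statistics and bookkeeping are correct under the stated
model, not that real-data name matching or duplicate detection is
solved.

## Problem sizes and numerical choices

The validation suite exercises the pipeline at 20,000 synthetic cases
(≈ 42,000 AE records), which gives planted pairs with λ ≥ 4 expected
counts well above 30 and leaves > 200 null pairs for the false-positive
measurement; property tests use 1,000 random tables against
brute-force oracles at 1e-9 and a 10⁶-draw Monte-Carlo check of the
gamma quantile at ±0.05. Determinism: every random draw flows from a
single integer seed; the same seed gives byte-identical packages.
Degenerate inputs are flagged, not guessed: empty comparator sides,
all-zero margins and non-computable statistics carry explicit markers
and can never be positive signals.

## Known limitations

* Signals are reporting associations, not incidence or causation;
  all the usual spontaneous-reporting caveats (under/over-reporting,
  notoriety effects, confounding by indication) apply to any real-data
  use.
* The published PT-level ROR/IC values for the real cohorts depend on
  the full multi-gigabyte FAERS download and on which IC estimator the
  original analysis used (unstated); they are therefore not
  reproduction targets here. The baseline (Table-level) statistics,
  which are fully determined by printed counts, are reproduced
  exactly.
* Only the modern quarterly ASCII schema is supported (no legacy SGML
  or pre-2012Q4 LAERS variants), and there is no fuzzy cross-CASEID
  duplicate detection.
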