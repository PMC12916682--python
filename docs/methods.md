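# Methods

This note documents the models and procedures implemented in
`faerspv`, the assumptions behind them, the defaults and why they were
chosen, what the synthetic data generator does and does not emulate,
and the numerical choices that matter for reproducibility.

## Unit of counting

Everywhere in the package the unit of counting is the **deduplicated
report**: one count per retained `primaryid`, never per PT row or per
case version. FAERS cases accumulate versions over time (same
`caseid`, new `primaryid`, later `fda_dt`); only the version with the
latest FDA receipt date is retained, with ties broken by the largest
`primaryid` (FAERS primary keys increase with later versions, so the
larger key is the newer record). Reports whose `caseid` is missing or
whose `fda_dt` is not a full 8-digit date cannot be grouped or ordered
and are dropped before deduplication; every drop is attributed to
exactly one reason in the cleaning log, so the manifest reconstructs
the report-selection flow with no unexplained losses.

## Cohorts

A cohort is the set of retained reports in which the target drug
appears with role code `PS` (Primary Suspect). Matching is **exact on
normalized tokens** (uppercase, whitespace collapsed, trailing
punctuation and dosage suffixes stripped) against a curated synonym
dictionary covering brand and generic names, applied to both
`drugname` and `prod_ai`. Substring matching was deliberately
rejected: it produces false hits on combination-product strings. The
dictionary is configuration (TSV), standing in for the manual
name-review step such studies perform.

## Demographics

Age is converted to years from its unit code (DEC ×10, YR ×1, MON
÷12, WK ÷52.1775, DY ÷365.25, HR ÷8766) and binned into
[0,2), [2,12), [12,18), [18,65), [65,85], (85,∞). The middle-bin
labels ("18–64", "65–85", ">85") imply 85 is inclusive in "65–85";
fractional ages bin by value. Missing age, sex and outcome values are
explicit categories in every descriptive table, never silently
dropped rows.

## Disproportionality statistics

The four statistics and their thresholds are described in the README.
Design choices that were genuinely open:

* **χ² continuity correction.** The PRR's χ² uses the Yates
  correction — standard in PRR pharmacovigilance practice and
  conservative near the χ² ≥ 4 threshold.
* **Zero cells.** ROR and PRR receive the Haldane–Anscombe +0.5
  correction on all four cells when any cell is zero (the result
  carries a `corrected` flag); IC and EBGM handle zeros natively
  through their own smoothing/shrinkage and are left untouched.
* **IC formulation.** The closed-form information-component
  credibility approximation
  (IC025 = IC − 3.3(a+0.5)^(−1/2) − 2.0(a+0.5)^(−3/2)) is the modern
  standard; the original neural-network variance propagation is out
  of scope.
* **Screening policy.** The frequentist screen is ROR-criterion *or*
  PRR-criterion; both flags are emitted per pair so an *and* policy is
  recomputable from the output without rerunning.
* **Background.** Expected counts compare each drug against **all
  other retained reports** in the cleaned dataset. No stratified
  (Mantel–Haenszel) expecteds and no multiplicity adjustment are
  applied — matching common practice for hypothesis-generating
  disproportionality screens.

## MGPS fitting

The five hyperparameters (α₁, β₁, α₂, β₂, P) maximize the marginal
likelihood Σ log[P·NB(a; α₁, β₁/(β₁+E)) + (1−P)·NB(a; α₂, β₂/(β₂+E))]
over all pairs with E > 0. Optimization is Nelder–Mead on
log/logit-transformed parameters (positivity and 0<P<1 hold by
construction), from the canonical start (0.2, 0.1, 2.0, 4.0, 1/3)
plus four seeded jitters; the best attained likelihood wins. No
count-squashing is used — the ensembles here are thousands of cells,
not millions. Fits on fewer than 50 usable tables warn; a fit in
which the two components' means merge warns but is still returned
(it is a legitimate boundary solution when the data carry a single
component). EBGM05 is found by `brentq` on the posterior-mixture CDF
with tolerance 1e−8 after doubling the bracket until it encloses the
5% point.

Level-specific priors: HLT/SOC signal tables **refit** the prior on
the aggregated-table ensemble by default, because aggregation changes
the count distribution; a `reuse` policy (apply the PT-level prior)
is available in configuration, and under it a single-PT HLT
reproduces its PT's statistics exactly.

## Hierarchy and immune classification

The PT→HLT→SOC mapping is a user-supplied, pre-flattened,
primary-path file (MedDRA itself is licensed); multiaxial secondary
paths are unsupported by design, for determinism. Roll-up uses
unique-report counting — a report maps to a term once if at least one
of its PTs belongs there — and unmapped PTs are reported in a
remainder file, never dropped. An HLT signal is *immune-related* if
any of its significant member PTs is on the direct watchlist
(type-I-hypersensitivity and local immune-inflammatory terms),
*immune-related-indirect* if only an indirect marker (e.g. steroid
therapy, indicating treatment of an inflammatory event) is present,
else *non-immune-related*. The shipped watchlists are starter files
and explicitly user-extensible; the package does not encode any
regulatory guidance document.

## Time-to-onset

TTO = event date − earliest therapy start date over THER rows linked
to the Primary-Suspect drug (`dsg_drug_seq = drug_seq`), in whole
days. Both dates must be complete 8-digit dates; partial dates and
negative intervals are excluded and counted in a completeness log.
Bins have inclusive upper edges: [0,30], [31,60], [61,90], [91,120],
[121,150], [151,180], [181,360], (360,∞). Percentages are rounded
half-up — 1 decimal for general tables, 2 decimals for TTO — which is
what lets printed tables be reproduced digit-for-digit from their
counts. Annual attribution uses the FDA receipt year (`fda_dt`),
matching the quarterly-file framing; event-date attribution is a
config option.

Time-stratified signal detection re-runs the full four-statistic
stack on the subset of reports assignable to a stratum (early ≤ 30
days, late > 360 days, or age-group/sex partitions), with the
background restricted to the stratum. Strata under 50 reports warn
and are skipped.

**Limitation — dominant cohorts inside strata.** Restricting the
background to a stratum caps the observed/expected ratio at
N_stratum / n_cohort. When one drug dominates a stratum (a late-onset
drug inside its own >360-day stratum can be ~half the stratum at desk
scale), EBGM05 > 2 becomes unattainable *by construction*, even for an
event exclusive to the drug, while ROR and IC remain informative. At
full-database scale a cohort is a fraction of a percent of the
background and no such cap binds. Stratified outputs therefore carry
all four statistics and per-criterion flags rather than only the
combined verdict.

## The synthetic generator

The generator emulates the statistical structure the analysis
assumes, with known ground truth:

* one Primary-Suspect drug per case, drawn from a per-drug volume
  table; the default is two target drugs (8,000 and 2,000 cases — the
  4:1 volume ratio typical of an older vs. newly launched agent) plus
  twenty background drugs of 2,000 cases each, ~50,000 cases total,
  spread uniformly over quarters 2019Q2–2025Q2;
* events drawn per vocabulary PT (39 terms, baselines 0.002–0.05) as
  independent Bernoulli trials whose **odds** are multiplied by the
  planted relative rate, so the generating-process ROR equals the
  configured RR and recovery tests are directly interpretable. A
  report with no hit draws one PT from its effective weights (every
  FAERS report has at least one event); this inflation is accounted
  for analytically in `expected_counts`;
* the planted profiles mirror the two study phenotypes: a late-onset
  skeletal/metabolic set (fractures RR 8, jaw osteonecrosis RR 12,
  hypocalcaemia RR 10, noninfective gingivitis RR 6, steroid therapy
  RR 5) on the larger drug with log-normal TTO median 400 d, σ 0.8;
  and an early-onset cardiovascular/injection-site set (myocardial
  infarction RR 8, cardiac failure RR 6, cerebrovascular accident
  RR 5, injection-site urticaria RR 10, erythema RR 6) on the smaller
  drug with TTO median 25 d, σ 0.8; background drugs use median 90 d,
  σ 1.2;
* duplicate case versions (rate 0.08) share a `caseid` with an
  incremented `primaryid` and strictly later `fda_dt` — the
  deduplication target; missingness defaults: age 0.5, sex 0.2,
  outcome 0.15, event date 0.15, in the range spontaneous-reporting
  data show;
* a synthetic PT→HLT→SOC hierarchy (39 PTs, 24 HLTs, 8 SOCs) and
  per-drug indication distributions (osteoporosis and subtypes for
  the targets, plus oncology indications for the larger drug).

All randomness flows from one seeded generator and rows are emitted
in fixed order, so a (config, seed) pair yields byte-identical files.

What it does **not** emulate: free-text drug-name noise beyond the
synonym list, correlated event co-reporting, reporting-rate drift
over calendar time, country- or reporter-specific event profiles, and
the multi-million-report scale of the real database. Passing recovery
tests therefore demonstrate that the pipeline's machinery is correct
under the generative assumptions, not that real-data signals at full
scale would be identical — in particular, absolute EBGM/IC magnitudes
depend on the background size and composition.

## Problem sizes and tolerances

The default test and acceptance battery uses the full ~50,000-case
synthetic study for end-to-end recovery, 5,000 simulated cells for
prior-recovery checks (fit must reach within 1.0 log-likelihood of
the generating prior), 200,000 Monte-Carlo draws × 20 tables for the
posterior-quantile cross-check (agreement within 0.02, with tables in
the modest-ratio regime where that tolerance exceeds the Monte-Carlo
oracle's own noise), and brute-force recount oracles on fixtures of
≤ 1,000 rows. Smaller `scale` factors of the same configuration serve
as quick fixtures.
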