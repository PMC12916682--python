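# faerspv

Disproportionality signal detection for FAERS-style spontaneous
adverse-event reports, built for comparative drug-safety studies such
as the denosumab vs. romosozumab osteoporosis-biologics comparison:
two monoclonal antibodies with different mechanisms (RANKL inhibition
vs. sclerostin inhibition), different onset profiles (late cumulative
vs. early acute), and different immune-related event spectra.

The package is aimed at pharmacovigilance analysts and methods
researchers who need the full desk workflow as tested, reusable code:

* **Ingestion** of FDA Adverse Event Reporting System (FAERS)
  quarterly ASCII tables (`$`-delimited DEMO, DRUG, REAC, OUTC, RPSR,
  THER, INDI), concatenated across quarters.
* **Cleaning**: the FDA-recommended deduplication rule (one report per
  case, latest `FDA_DT` retained), demographic normalization, and
  Primary-Suspect cohorting through a curated drug-synonym dictionary.
* **Signal detection** with four algorithms on each drug–event 2×2
  table and the combined confirmation criterion.
* **MedDRA-style roll-up** of Preferred-Term signals to High-Level
  Term and System Organ Class, with immune-related classification of
  HLT signals against editable watchlists.
* **Descriptive reporting**: annual, geographic, demographic,
  reporting-source, outcome and indication tables; time-to-onset
  binning; time-stratified signal detection.
* A **synthetic FAERS generator** with planted ground truth, so every
  stage is testable end-to-end without downloading anything.

## The statistics

For a drug–event pair, let `a` = reports with the drug (as Primary
Suspect) and the event, `b` = drug without event, `c` = event without
drug, `d` = neither, `N = a+b+c+d`, and `E = (a+b)(a+c)/N` the count
expected under independence.

* **ROR** = `ad/bc`, with Woolf 95% CI
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`; screen: lower CI > 1 and `a ≥ 3`.
* **PRR** = `[a/(a+b)]/[c/(c+d)]` with Yates-corrected
  `χ² = N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)]`; screen: PRR ≥ 2,
  χ² ≥ 4, `a ≥ 3`.
* **BCPNN information component** `IC = log₂[(a+0.5)/(E+0.5)]` with
  the closed-form credibility bound
  `IC025 = IC − 3.3(a+0.5)^(−1/2) − 2.0(a+0.5)^(−3/2)`; gate: IC025 > 0.
* **MGPS EBGM**: an empirical-Bayes gamma–Poisson shrinker. The
  relative reporting rate λ has a two-component gamma mixture prior
  `P·Γ(α₁,β₁) + (1−P)·Γ(α₂,β₂)` whose five hyperparameters are fit by
  maximizing the negative-binomial marginal likelihood over all pairs.
  The posterior is again a gamma mixture;
  `EBGM = exp E[ln λ | a]` (via the digamma function) and EBGM05 is
  the posterior 5th percentile by bracketed root-finding; gate:
  EBGM05 > 2.

A **confirmed signal** passes the frequentist screen (ROR criterion
*or* PRR criterion) *and* both Bayesian gates.

## Worked example

Generate a synthetic study (a 10% scale of the default conditions)
and run the full pipeline:

```bash
faerspv simulate --out demo_sim --seed 42 --scale 0.1
# wrote 187 quarterly files and truth.json to demo_sim (5000 cases)

cat > demo_cfg.json <<'JSON'
{
  "input_dir": "demo_sim",
  "output_dir": "demo_out",
  "drug_dictionary": "demo_sim/drug_dictionary.tsv",
  "targets": ["DENOSUMAB", "ROMOSOZUMAB"],
  "hierarchy": "demo_sim/hierarchy.tsv",
  "seed": 42
}
JSON
faerspv run --config demo_cfg.json
```

prints the manifest counts —

```
{
 "cohort_sizes": {"DENOSUMAB": 800, "ROMOSOZUMAB": 200},
 "deduplicated_reports": 5000,
 "dropped": {"superseded_case_versions": 418},
 "raw_reports": 5418
}
```

5,418 raw report versions collapse to exactly 5,000 unique cases (418
were superseded case versions planted by the generator), and the two
Primary-Suspect cohorts match the generator's volumes.  `demo_out/`
then holds per-drug PT/HLT/SOC signal CSVs, descriptive tables,
time-to-onset tables, stratified signal tables and the immune
classification.

The statistics themselves, on the worked 2×2 table
`(a,b,c,d) = (5, 95, 100, 9800)`:

```python
from faerspv import ContingencyTable, compute_ror, compute_prr, compute_ic
t = ContingencyTable(5, 95, 100, 9800)
compute_ror(t)   # (5.158, 2.054, 12.95, True, False)
compute_prr(t)   # (4.950, 11.57, True, False)
compute_ic(t)    # (1.827, 0.265, True)
```

i.e. the drug–event pair is reported ~5× more often than expected,
with all intervals clear of their thresholds, so the pair passes the
screen and the IC gate.

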