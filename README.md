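# faerspv

Pharmacovigilance signal detection on FAERS-style spontaneous-report data.

The package ingests FDA Adverse Event Reporting System (FAERS/LAERS)
quarterly ASCII extracts, normalizes drug names to molecular ingredients and
adverse-reaction strings to preferred terms, removes exact-duplicate
reports, and computes disproportionality statistics — globally and per
calendar month — together with analyses of the reporting biases that
contaminate spontaneous-report data. A seeded synthetic-corpus generator
with planted ground truth makes every stage testable without the external
FAERS download.

## Components

| module | purpose |
| --- | --- |
| `faerspv.model` | report/case data model, FAERS quarterly ASCII parsers (legacy LAERS and 2012Q4+ layouts), normalized TSV round-trip |
| `faerspv.synth` | seeded FAERS-like corpus generator: planted drug–ADR associations, synonym fragmentation, duplicates, indication conflation, occupation drift, month-localized spikes |
| `faerspv.ingredients` | verbatim drug name → ingredient key mapping by token-set Tanimoto (thresholds 0.2 fuzzy / 0.99 exact), manual overrides |
| `faerspv.meddra` | verbatim ADR/indication → preferred term by normalized Levenshtein similarity (0.95 perfect / 0.90 minimum), manual overrides |
| `faerspv.dedup` | exact-duplicate detection over (ingredients, PTs, event date, age, sex) fingerprints; optional collapsing |
| `faerspv.signals` | contingency tables, relative reporting ratio (RRR), Yates-corrected χ² p-values, Holm q-values, the N≥5 / q<0.05 / RRR>1 signal filter, stratified expected counts, gamma-Poisson empirical-Bayes shrinkage (EBGM/EB05/EB95) |
| `faerspv.timeseries` | month-resolved signal tables (within-month Holm), per-month ADR composition, k-medoids clustering of RRR trajectories under 1 − Pearson r |
| `faerspv.bias` | indication–ADR conflation detection, reporter-occupation composition, outcome distributions, logistic regression (IRLS), exposure-margin classification |
| `faerspv.cli` | `faerspv` command-line entry point wiring the stages |

## Command line

```sh
# generate a synthetic corpus with ground truth
faerspv simulate --n-reports 10000 --duplicate-fraction 0.02 --seed 7 --out runs/sim

# parse a quarterly extract ($-delimited DEMO/DRUG/REAC/INDI/OUTC tables)
faerspv ingest --demo DEMO.txt --drug DRUG.txt --reac REAC.txt \
    --indi INDI.txt --outc OUTC.txt --dialect legacy_LAERS --out runs/q1

# normalize, deduplicate, score
faerspv map-drugs --corpus runs/q1 --synonyms synonyms.tsv --out runs/q1m
faerspv normalize-adrs --corpus runs/q1m --vocabulary vocabulary.txt --out runs/q1n
faerspv dedup --corpus runs/q1n --collapse --out runs/q1d
faerspv signals --corpus runs/q1d/deduplicated --eb --out runs/signals
faerspv monthly --corpus runs/q1d/deduplicated --start 2004-01 --end 2005-12 --out runs/monthly
faerspv clusters --monthly-table runs/monthly/monthly_signals.tsv --ingredient ING-0001 --k 3 --out runs/clusters
faerspv biases --corpus runs/q1d/deduplicated --out runs/biases

# or everything in one shot on packaged fixtures
faerspv pipeline --demo ... --synonyms ... --vocabulary ... --out runs/full
```

Every run writes a manifest (config echo, input digests, package version)
next to its outputs. A small fixture quarter, synonym table and vocabulary
ship under `faerspv/data/` for smoke testing.

File formats: synonym tables are `synonym<TAB>key[;key...]` lines,
vocabularies one preferred term per line, normalized corpora a directory of
three TSV tables (`reports.tsv`, `report_drugs.tsv`,
`report_reactions.tsv`) plus `corpus.json`.

## Notes

- Full-scale FAERS results require the public FAERS snapshot (a rolling
  multi-gigabyte download), which is deliberately out of scope here; all
  statistical behavior is validated on synthetic corpora with planted
  ground truth.
- Holm's procedure controls the family-wise error rate; the signal filter
  uses it exactly as specified even where "FDR" is the colloquial label.
- `eb_scores` posterior quantiles are solved to 1e-8 on the mixture CDF;
  the EB prior fit is multi-start and deterministic given a seed.
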